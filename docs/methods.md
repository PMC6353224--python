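# Methods

## Model

The package implements an equilibrium statistical-thermodynamic model of
transcription driven by the Or59b regulatory cluster.  Five DNA sites — the
Acj6 and Pdm3 Homeobox sites, a single shared Pou site, the Ebox and the
TATA box — are jointly occupied by the two-domain Pou-Homeobox proteins
Acj6 (domains A1/A2) and Pdm3 (B1/B2), the bHLH activator Fer1 (C) and RNA
polymerase (R).  Because the Pou site holds at most one domain, the state
space has 2·2·3·2·2 = 48 configurations.  Each configuration's unnormalised
weight is the product of

- the affinity ratios `q_j = [j]/K_j` of its occupied sites (bound/unbound
  odds; `K_j` is the half-occupancy concentration of the Hill relation);
- interaction factors for co-bound pairs: cooperativities `wA1A2`, `wB1B2`
  (double binding of one protein across Homeobox + Pou), competitions
  `wA1B2`, `wB1A2` (a Homeobox-bound protein against the other protein on
  the Pou site), and the Fer1–RNAp cooperativity `wCR`;
- epigenetic factors applied to Fer1-bound configuration classes: `h1`
  (Fer1 alone on the cluster), `h2` (Fer1 with Homeobox-bound TFs but an
  empty Pou site), `h3` (Fer1 with an occupied Pou site), and `hA`/`hB`
  (remodulation of the respective double-binding cooperativity when Fer1 is
  bound).  One full set of five exists per chromatin background: normal
  (C), heterozygous (H) and homozygous (N) su(var)3-9 mutant, i.e.
  progressively more open chromatin.

The observable is the probability that RNAp occupies the TATA box — the
normalised weight of the 24 RNAp-bound configurations — identified with
cluster-driven expression on a 0–1 scale.

**The bare-Fer1 exception.**  `wCR` does not act in the configuration where
Fer1 is the only protein on the cluster (σ45 = C+R).  Physically: without a
stabilising partner (any Homeobox- or Pou-bound TF), Fer1's residence on
the Ebox is too transient to recruit the polymerase.  This exception is
load-bearing: since every RNAp-bound state is its RNAp-free mirror times
`qR` (times `wCR` when Fer1 co-recruits), strong expression in the
Pdm3Hox-mutant row forces `qR·wCR ≥ 1.5`, while the "only Ebox intact"
experiment must stay silent; both cannot hold if bare Fer1 enjoys the full
cooperativity.  With the exception in place the admissible parameter region
reproduces the expected ensemble structure: `qC` pinned to a narrow window
(roughly 400–700), `qR·wCR` near its maximum, `qA ≪ qB`, and the
single-site-mutant rows expressing through σ38 (Acj6 doubly bound + Fer1),
σ37/σ9 (Pdm3 doubly bound) and σ48 (both Homeobox sites + Fer1)
respectively.

**h3 scope.**  `h3` applies to every Fer1-bound, Pou-occupied
configuration, including the double-binding ones (σ13–σ20 and σ37–σ44); the
effective double-binding enhancements are therefore `hA·h3` and `hB·h3`.

## Experimental design and mutations

The truth table enumerates the four motif mutations in binary order (row 1
= all mutated … row 16 = intact) against the three chromatin columns; each
cell holds an interval [ℓ, u] of admissible normalised expression.
Ebox-mutated rows, and the row where only the Ebox is intact, are
total-loss cells [0, 0.1]; unmeasured cells carry the maximal interval
[0, 1].  A mutated motif retains a residual affinity drawn from
[10⁻⁶, 10⁻⁵] (default 10⁻⁵·⁵, the log-midpoint; results are insensitive
within the range); a Pou mutation silences both `qA2` and `qB2` because the
two domains share one site.  TF-knockout proxies are represented purely by
their mutation patterns.

## Fitting

The cost Φ sums, over the requested conditions, the Euclidean distance of
the predicted binding probability from the cell's interval; a parameter set
is *feasible* when Φ = 0.  The cost is piecewise-smooth and highly
multiplicative, with no useful gradient structure, so inference is by
staged rejection sampling:

1. draw the 11 q/w parameters uniformly within their ranges, rejecting
   (qA1, qA2) and (qB1, qB2) pairs whose product leaves (0.1, 2500);
2. draw epigenetic factors from Normal(mean, mean/10), truncated positive —
   by default one independent realisation per truth-table cell (see below);
3. retain samples with Φ^C < τ and Φ^H < τ, τ = 0.05;
4. draw N-column factors around their nominal values with the monotone
   C→H→N trend enforced on the H→N leg per sample (h2, h3, hA increase as
   chromatin opens; h1, hB decrease), and score Φ^N and full feasibility.

`tune_h` formalises the nominal-value retuning of the validation stage as a
seeded multiplicative random walk over one column's nominals, scored by the
filtered fraction of a fixed q/w evaluation set and constrained to the
monotone trend; passing the retained samples of a C/H fit as the evaluation
set reproduces the protocol in which binding and interaction parameters are
frozen and only the epigenetic background is allowed to track chromatin
state.  `revalidate_n_column` then rescores an ensemble under the tuned
nominals.

**Per-condition epigenetic draws.**  Each truth-table cell summarises a
separately raised fly cohort, so the cell's effective epigenetic background
is its own random realisation; the model draws one h vector per cell (per
chromatin column) rather than one per column.  This choice is also forced
internally: with a single shared draw, the model's predictions for the
"Acj6Hox+Ebox intact" and "Pou mutated" rows are ordered the wrong way
around for every parameter value (the latter's state set strictly contains
the former's), making exact feasibility impossible.  A `h_draw_scope`
switch restores the shared-draw variant.

**Importance sampling.**  The admissible q/w region occupies roughly
10⁻⁷–10⁻⁸ of the prior box, so plain uniform sampling cannot populate the
retained ensemble in reasonable time.  The `sampling="importance"` mode
draws each parameter from a mixture of a focus window and the full range,
refines the windows at run time by cross-entropy iterations (elite samples
ranked by Φ^C + Φ^H at nominal h, with pruning), and corrects the retained
set back to the uniform law with self-normalised importance weights,
truncated at √n times their mean for variance control.  The estimand — any
weighted fraction over the retained set — is exactly what a uniform run
would measure; only the variance changes.  Only the q/w proposal adapts;
the epigenetic draw law is a study condition and is never tuned.

Two exact accelerations keep budgets small: rows are evaluated
most-selective-first and a sample is dropped as soon as its partial Φ
reaches τ (Φ is a sum of nonnegative terms), and the theorem
`P_binding ≤ qR·wCR/(1+qR·wCR)` pre-gates samples whose polymerase gain
cannot reach the strong-expression rows.

## Synthetic data and recovery

`generate_truth_table` pushes a documented ground-truth parameter set
through the forward model and surrounds each cell's value with a symmetric
±δ interval clipped to [0, 1] (default δ = 0.1, comparable to the
experimental interval widths; optional uniform jitter of interval centres
for robustness checks, off by default because the experimental intervals
encode replicate spread rather than a known noise law).  The shipped ground
truth sits at a realistic operating point — near-maximal polymerase gain,
mid-range `qC`, asymmetric domain splits with `qA ≪ qB` — so the synthetic
table exercises both silent and strongly expressing cells.  The ground
truth is feasible on its own table by construction (exactly, since the
generator and the cost use the same forward model at nominal h).
`recovery_experiment` fits the synthetic table and reports the feasible
fraction, whether the truth passes feasibility, and per-parameter feasible
marginals against the prior.

What passing synthetic tests does and does not show: they validate the
pipeline end-to-end (forward model, interval construction, staged filter,
bookkeeping) under the model's own assumptions; they do not probe
mis-specification — real expression measurements aggregate counting noise,
normalisation error and genuine biological heterogeneity that the interval
representation only bounds.

## Numerical choices

- Weights are computed as sums of log-factors; probabilities exponentiate
  relative to the per-sample maximum log-weight (parameter ranges span ~9
  orders of magnitude).  Batch internals run in float32 — distances live on
  the 0.01–1 scale, far above float32 resolution — while all bookkeeping
  stays float64.
- Dominant states are argmaxes of the ensemble-mean state probabilities,
  separately over RNAp-bound ("on") and RNAp-free ("off") blocks, ties
  broken to the lowest canonical index.  When an ensemble holds no
  exactly-feasible sample, summaries can be computed over the lowest-cost
  retained subset (`subset="best"`), which is reported as such.
- The canonical σ ordering is frozen and shipped as
  `data/state_table.csv`; indices 1–24 have the TATA box empty and k+24 is
  k plus RNAp.  Reports carry occupancy descriptions alongside indices
  because a handful of placements are conventional.
- Strict inequalities for the monotone epigenetic trend; ties rejected.
- Seeded `numpy` Generators drive every random stage; fits are
  bit-reproducible for a fixed configuration.

## Known limitations

- Equilibrium only: no binding kinetics, no explicit chromatin-remodelling
  dynamics; the chromatin state enters solely through the h factors.
- Exact feasibility on the experimental table is much rarer in this
  implementation (of order 10⁻⁴–10⁻⁵ of retained samples; typically zero in
  a few-minute run) than the ~0.5% the original analysis reports.  The gap
  traces to three cells (the double-Hox-mutant, Pdm3-knockdown and
  intact-cluster rows) that sit a few hundredths outside their intervals at
  the cost-optimal corner and are closed only by fortunate joint epigenetic
  draws; the exact per-state weight assignments that would close them
  structurally are not recoverable from the available description.  The
  N-column validation fraction, the ensemble's parameter structure and the
  dominant-state assignments are robust to this.
- Identifiability is not addressed: the feasible ensemble characterises the
  admissible region, not a posterior.
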