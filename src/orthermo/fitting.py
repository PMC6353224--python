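"""Interval-constrained random-search parameter fitting.

The cost of a parameterisation is the summed Euclidean set distance of the
predicted RNAp-binding probability from the admissible interval over the
requested truth-table conditions:

    Φ = Σ_ji d(P_binding(θ_ji), [ℓ_ji, u_ji]),   d(x, [ℓ,u]) = max(ℓ−x, x−u, 0)

A parameter set is *feasible* when Φ = 0, i.e. every prediction falls inside
its interval.  No effective gradient-type minimiser exists for this
piecewise-smooth, highly multiplicative cost, so fitting is by staged
rejection sampling:

(i)   draw q/w uniformly within their ranges (rejecting draws whose
      qA1·qA2 or qB1·qB2 product leaves the admissible product range) and
      epigenetic factors around the nominal C and H values — by default one
      independent draw per truth-table cell, modelling the separately raised
      fly cohorts behind the different experiments;
(ii)  retain samples with Φ^C < τ and Φ^H < τ (τ = 0.05 by default);
(iii) mark as feasible-CH the retained samples inside every C and H interval;
(iv)  draw the N-column epigenetic factors around their nominal values,
      enforcing the monotone C→H→N trend on the H→N leg, and score Φ^N and
      full 48-condition feasibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import engine
from .params import (
    BindingAffinities,
    ChromatinState,
    DEFAULT_RESIDUAL,
    EpigeneticFactors,
    H_NAMES,
    InteractionFactors,
    NOMINAL_H,
    ParameterSet,
    QA_QB_PRODUCT_RANGE,
    QW_RANGES,
    Q_NAMES,
    W_NAMES,
)
from .truth_table import (
    ExpressionInterval,
    TruthTable,
    all_conditions,
    condition_pbinding,
)

__all__ = [
    "FitConfig",
    "FitEnsemble",
    "set_distance",
    "phi",
    "sample_qw",
    "sample_qw_arrays",
    "perturb_h",
    "check_h_monotonicity",
    "run_fit",
    "revalidate_n_column",
    "tune_h",
]

# h components that must increase (resp. decrease) as chromatin opens C→H→N.
H_INCREASING: Tuple[str, ...] = ("h2", "h3", "hA")
H_DECREASING: Tuple[str, ...] = ("h1", "hB")

_QW_NAMES: Tuple[str, ...] = Q_NAMES + W_NAMES
_QA1, _QA2 = Q_NAMES.index("qA1"), Q_NAMES.index("qA2")
_QB1, _QB2 = Q_NAMES.index("qB1"), Q_NAMES.index("qB2")
_H_INC_MASK = np.array([name in H_INCREASING for name in H_NAMES])

# Focus windows of the importance-sampling proposal for the q/w search.
# The admissible region compatible with the strong-expression rows is a thin
# corner of the prior box (the polymerase gain qR·wCR must approach its
# maximum for the Pdm3Hox-mutant row; the Fer1 affinity qC is pinned to a
# narrow window by the Pou-mutant and double-Hox rows; the two-domain TFs
# must split their affinity asymmetrically, Hox-heavy for Acj6 and Pou-heavy
# for Pdm3).  Each parameter is proposed from a mixture
#   p·Uniform(focus window) + (1−p)·Uniform(full range)
# whose density is known exactly, so self-normalised importance weights
# reproduce the plain uniform law without bias; parameters without an entry
# are proposed uniformly.  The windows derive from the model's structure
# (see docs/methods.md), not from any fitted ensemble.
IMPORTANCE_FOCUS: Mapping[str, Tuple[float, float, float]] = {
    # name: (mixture weight on focus, focus low, focus high)
    "qR": (0.7, 0.02, 0.03),
    "wCR": (0.7, 60.0, 100.0),
    "qC": (0.7, 200.0, 800.0),
    "qA1": (0.7, 1000.0, 2500.0),
    "qA2": (0.7, 0.1, 2.5),
    "qB1": (0.7, 0.1, 5.0),
    "qB2": (0.7, 800.0, 2500.0),
    "wA1A2": (0.5, 30.0, 100.0),
    "wB1B2": (0.5, 50.0, 100.0),
}


def set_distance(x: float, interval: ExpressionInterval) -> float:
    """Euclidean distance of a point from an interval: max(ℓ−x, x−u, 0)."""
    return interval.distance(x)


def phi(
    params: ParameterSet,
    table: TruthTable,
    columns: Iterable[ChromatinState] = tuple(ChromatinState),
    residual: float = DEFAULT_RESIDUAL,
) -> float:
    """Total cost Φ over the requested chromatin columns (scalar path).

    Φ^C, Φ^H, Φ^N are the single-column restrictions; Φ = 0 iff every
    evaluated condition's P_binding lies inside its interval.  Uses the
    parameter set's own epigenetic values (no perturbation).
    """
    total = 0.0
    cols = set(columns)
    for condition in all_conditions():
        if condition.chromatin not in cols:
            continue
        p = condition_pbinding(params, condition, residual=residual)
        total += set_distance(p, table.interval(condition))
    return total


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the staged random search.

    ``total_samples`` caps the raw q/w draws; if ``target_retained`` is set,
    batches are drawn until that many samples survive the C/H filter (or the
    cap is hit).  ``h_rel_sd`` is the relative standard deviation of the
    epigenetic draws (Normal(mean, mean·h_rel_sd), redrawn if nonpositive).
    ``h_draw_scope`` selects whether one epigenetic realisation is drawn per
    truth-table cell ("condition", the default — each cell summarises a
    separately raised cohort) or shared across a column ("column").
    """

    ranges: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: dict(QW_RANGES))
    nominal_h: Mapping[ChromatinState, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(NOMINAL_H[s]) for s in ChromatinState}
    )
    tau: float = 0.05
    batch_size: int = 100_000
    total_samples: int = 1_000_000
    target_retained: Optional[int] = None
    seed: int = 0
    residual: float = DEFAULT_RESIDUAL
    h_rel_sd: float = 0.1
    h_draw_scope: str = "condition"
    sampling: str = "uniform"
    adapt_proposal: bool = True
    adapt_iters: int = 5
    adapt_samples: int = 120_000
    adapt_elite: int = 300
    log_uniform: bool = False
    enforce_monotonicity_global: bool = False
    keep_pbinding: bool = True

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.h_draw_scope not in ("condition", "column"):
            raise ValueError("h_draw_scope must be 'condition' or 'column'")
        if self.sampling not in ("uniform", "importance"):
            raise ValueError("sampling must be 'uniform' or 'importance'")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")

    def nominal(self, chromatin: ChromatinState) -> EpigeneticFactors:
        return EpigeneticFactors(**dict(self.nominal_h[chromatin]))

    def nominal_vector(self, chromatin: ChromatinState) -> np.ndarray:
        return np.array([self.nominal_h[chromatin][name] for name in H_NAMES])


def _uniform(rng: np.random.Generator, lo: float, hi: float, n: int, log_scale: bool) -> np.ndarray:
    if log_scale:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    return rng.uniform(lo, hi, n)


def _draw_param(
    config: FitConfig,
    name: str,
    n: int,
    rng: np.random.Generator,
    focus: Optional[Mapping[str, Tuple[float, float, float]]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw one parameter for n samples; returns (values, log importance weight).

    Under uniform sampling the log weight is zero.  Under importance
    sampling, parameters with a focus window are drawn from the mixture
    p·U(focus) + (1−p)·U(full); the log ratio of the uniform density to the
    mixture density is returned so that self-normalised reweighting
    reproduces the uniform law exactly.
    """
    lo, hi = config.ranges[name]
    if focus is None and config.sampling == "importance":
        focus = IMPORTANCE_FOCUS
    use_importance = (
        config.sampling == "importance"
        and focus is not None
        and name in focus
        and not config.log_uniform
    )
    if not use_importance:
        return _uniform(rng, lo, hi, n, config.log_uniform), np.zeros(n)
    p, flo, fhi = focus[name]
    flo, fhi = max(flo, lo), min(fhi, hi)
    in_focus = rng.random(n) < p
    vals = np.where(in_focus, rng.uniform(flo, fhi, n), rng.uniform(lo, hi, n))
    density = p / (fhi - flo) * ((vals >= flo) & (vals <= fhi)) + (1 - p) / (hi - lo)
    return vals, -np.log(density * (hi - lo))


def _sample_constrained_pair(
    config: FitConfig,
    names: Tuple[str, str],
    n: int,
    rng: np.random.Generator,
    focus: "Optional[Mapping[str, Tuple[float, float, float]]]" = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """n (q1, q2) pairs, each drawn within its range and rejected until the
    product lies inside the admissible product range; returns (pairs, log w).

    The acceptance probability of a raw uniform pair is small (~0.3% for the
    shipped ranges), so candidates are drawn in pools sized by the running
    acceptance estimate rather than one redraw round per rejection.  The
    truncation normalisation constants cancel under self-normalised
    importance weighting.
    """
    lo_p, hi_p = QA_QB_PRODUCT_RANGE
    out = np.empty((n, 2))
    logw = np.empty(n)
    filled = 0
    accept_est = 0.004 if config.sampling == "uniform" else 0.05
    while filled < n:
        m = max(int((n - filled) / accept_est * 1.1), 4096)
        m = min(m, 4_000_000)
        q1, lw1 = _draw_param(config, names[0], m, rng, focus)
        q2, lw2 = _draw_param(config, names[1], m, rng, focus)
        prod = q1 * q2
        ok = (prod > lo_p) & (prod < hi_p)
        k = int(ok.sum())
        take = min(k, n - filled)
        sel = np.where(ok)[0][:take]
        out[filled : filled + take, 0] = q1[sel]
        out[filled : filled + take, 1] = q2[sel]
        logw[filled : filled + take] = lw1[sel] + lw2[sel]
        filled += take
        if k:
            accept_est = max(k / m, 5e-4)
    return out, logw


def _sample_qw_weighted(
    config: FitConfig,
    n: int,
    rng: np.random.Generator,
    focus: "Optional[Mapping[str, Tuple[float, float, float]]]" = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """(n, 11) q/w draws plus per-sample log importance weights."""
    out = np.empty((n, len(_QW_NAMES)))
    logw = np.zeros(n)
    pair_a, lw_a = _sample_constrained_pair(config, ("qA1", "qA2"), n, rng, focus)
    pair_b, lw_b = _sample_constrained_pair(config, ("qB1", "qB2"), n, rng, focus)
    logw += lw_a + lw_b
    for i, name in enumerate(_QW_NAMES):
        if name == "qA1":
            out[:, i] = pair_a[:, 0]
        elif name == "qA2":
            out[:, i] = pair_a[:, 1]
        elif name == "qB1":
            out[:, i] = pair_b[:, 0]
        elif name == "qB2":
            out[:, i] = pair_b[:, 1]
        else:
            vals, lw = _draw_param(config, name, n, rng, focus)
            out[:, i] = vals
            logw += lw
    return out, logw


def sample_qw_arrays(config: FitConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n q/w samples as an (n, 11) array in ``Q_NAMES + W_NAMES`` order.

    Marginals are uniform within each parameter's range; the (qA1, qA2) and
    (qB1, qB2) pairs are rejection-sampled until their products fall inside
    the admissible product range, which preserves the stated uniform joint
    law restricted to the admissible region (the two pairs are independent,
    so per-pair rejection equals joint rejection in distribution).  Always
    uses plain uniform sampling regardless of ``config.sampling``.
    """
    uniform_config = config if config.sampling == "uniform" else replace_sampling(config)
    arr, _ = _sample_qw_weighted(uniform_config, n, rng)
    return arr


def replace_sampling(config: FitConfig, sampling: str = "uniform") -> FitConfig:
    """Copy of a config with a different sampling mode."""
    from dataclasses import replace

    return replace(config, sampling=sampling)


def sample_qw(
    config: FitConfig, n: int, seed: Optional[int] = None
) -> List[Tuple[BindingAffinities, InteractionFactors]]:
    """Object-level wrapper around :func:`sample_qw_arrays` (for small n)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arr = sample_qw_arrays(config, n, rng)
    draws = []
    for row in arr:
        q = BindingAffinities(**{name: float(row[i]) for i, name in enumerate(Q_NAMES)})
        w = InteractionFactors(
            **{name: float(row[len(Q_NAMES) + i]) for i, name in enumerate(W_NAMES)}
        )
        draws.append((q, w))
    return draws


def _gaussian_h(
    means: np.ndarray, shape: Tuple[int, ...], rng: np.random.Generator, rel_sd: float
) -> np.ndarray:
    """Truncated-positive Normal(mean, mean·rel_sd) draws broadcast to shape."""
    if rel_sd == 0.0:
        return np.broadcast_to(means, shape).copy()
    draws = rng.normal(means, means * rel_sd, size=shape)
    bad = draws <= 0.0
    while bad.any():  # ~1e-23 per component at rel_sd=0.1; loop for safety
        means_b = np.broadcast_to(means, shape)
        draws[bad] = rng.normal(means_b[bad], means_b[bad] * rel_sd)
        bad = draws <= 0.0
    return draws


def perturb_h(
    nominal: EpigeneticFactors,
    n: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    rel_sd: float = 0.1,
) -> np.ndarray:
    """n Gaussian draws around nominal h values, shape (n, 5) in ``H_NAMES`` order.

    Each component is Normal(mean, mean·rel_sd), redrawn while nonpositive.
    ``rel_sd = 0`` returns the nominal values exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    means = np.array([getattr(nominal, name) for name in H_NAMES])
    return _gaussian_h(means, (n, len(H_NAMES)), rng, rel_sd)


def check_h_monotonicity(
    hC: EpigeneticFactors, hH: EpigeneticFactors, hN: EpigeneticFactors
) -> bool:
    """Strict monotone trend across chromatin opening: h2, h3, hA increase
    C→H→N; h1, hB decrease.  Ties fail."""
    for name in H_INCREASING:
        if not (getattr(hC, name) < getattr(hH, name) < getattr(hN, name)):
            return False
    for name in H_DECREASING:
        if not (getattr(hC, name) > getattr(hH, name) > getattr(hN, name)):
            return False
    return True


def _draw_h_n_monotone(
    nominal_n: np.ndarray,
    hH: np.ndarray,
    rng: np.random.Generator,
    rel_sd: float,
    max_redraws: int = 200,
) -> np.ndarray:
    """N-column h draws with the H→N leg of the trend enforced per component.

    Components violating the required ordering against the matching H-column
    draw are rejection-redrawn; after ``max_redraws`` rounds any stragglers
    are clipped just beyond the H value (rare for the shipped nominal values,
    where the ordering gaps are one to several standard deviations).
    """
    draws = _gaussian_h(nominal_n, hH.shape, rng, rel_sd)
    nominal_b = np.broadcast_to(nominal_n, hH.shape)
    for _ in range(max_redraws):
        bad = (draws <= 0.0) | np.where(_H_INC_MASK, draws <= hH, draws >= hH)
        if not bad.any():
            break
        draws[bad] = rng.normal(nominal_b[bad], nominal_b[bad] * rel_sd)
    bad = (draws <= 0.0) | np.where(_H_INC_MASK, draws <= hH, draws >= hH)
    if bad.any():
        eps = 1e-6
        clip = np.where(_H_INC_MASK, hH * (1 + eps), hH * (1 - eps))
        draws[bad] = clip[bad]
    return draws


@dataclass
class FitEnsemble:
    """Retained samples of a staged fit, with acceptance bookkeeping.

    ``samples`` has one row per retained sample (Φ^C < τ and Φ^H < τ): the 11
    q/w values, per-column epigenetic summaries (``h*_C/H/N``; the mean over
    rows when draws are per condition), the three Φ columns, feasibility
    flags and — unless disabled — the 48 per-condition P_binding values
    (``pb_{C,H,N}{row}``).  ``h_draws`` holds the actual epigenetic
    realisations per column, shaped (n_retained, 16, 5) for per-condition
    scope or (n_retained, 5) for column scope.
    """

    samples: pd.DataFrame
    n_sampled: int
    n_retained: int
    n_feasible_ch: int
    n_feasible_all: int
    config: FitConfig
    h_draws: Dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: Dict[str, float] = field(default_factory=dict)

    @property
    def n_filtered_out(self) -> int:
        return self.n_sampled - self.n_retained

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_sampled if self.n_sampled else math.nan

    @property
    def weights(self) -> np.ndarray:
        """Truncated self-normalised importance weights of the retained samples.

        Uniform sampling yields equal weights; under importance sampling the
        weights correct the retained set back to the plain-uniform law, so
        weighted retained-set fractions estimate the same conditional
        quantities a uniform run would produce.  Weights are truncated at
        √n times their mean before renormalising — the standard variance
        control for self-normalised estimators, whose bias vanishes with the
        sample size while preventing a single heavy-weight draw from
        dominating a fraction estimate.
        """
        if self.n_retained == 0:
            return np.empty(0)
        if "log_weight" not in self.samples:
            return np.full(self.n_retained, 1.0 / self.n_retained)
        lw = self.samples["log_weight"].to_numpy()
        w = np.exp(lw - lw.max())
        w /= w.sum()
        w = np.minimum(w, np.sqrt(w.size) * w.mean())
        return w / w.sum()

    @property
    def effective_sample_size(self) -> float:
        """Kish effective sample size of the retained, weighted ensemble."""
        w = self.weights
        if w.size == 0:
            return 0.0
        return float(1.0 / np.square(w).sum())

    @property
    def fraction_phiN_pass(self) -> float:
        """Weighted fraction of retained samples with Φ^N < τ (N-validation rate)."""
        if self.n_retained == 0:
            return math.nan
        passed = (self.samples["phi_N"] < self.config.tau).to_numpy()
        return float(self.weights @ passed)

    @property
    def fraction_feasible_all(self) -> float:
        """Weighted fraction of retained samples inside all 48 intervals."""
        if self.n_retained == 0:
            return math.nan
        return float(self.weights @ self.samples["feasible_all"].to_numpy(dtype=float))

    @property
    def feasible_mask(self) -> np.ndarray:
        return self.samples["feasible_all"].to_numpy(dtype=bool)

    @property
    def feasible(self) -> pd.DataFrame:
        """Retained samples satisfying every interval of the full truth table."""
        return self.samples[self.samples["feasible_all"]]

    def parameter_set(self, row_index: int) -> ParameterSet:
        """Reconstruct a ParameterSet for one retained sample.

        With per-condition epigenetic draws the h values are the sample's
        across-row means (one summary set per column); use ``h_draws`` for
        the exact per-condition realisations.
        """
        row = self.samples.loc[row_index]
        q = BindingAffinities(**{name: float(row[name]) for name in Q_NAMES})
        w = InteractionFactors(**{name: float(row[name]) for name in W_NAMES})
        eps = {
            state: EpigeneticFactors(
                **{name: float(row[f"{name}_{state.value}"]) for name in H_NAMES}
            )
            for state in ChromatinState
        }
        return ParameterSet(affinities=q, interactions=w, epigenetics=eps)

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def _h_shape(config: FitConfig, n: int) -> Tuple[int, ...]:
    if config.h_draw_scope == "condition":
        return (n, 16, len(H_NAMES))
    return (n, len(H_NAMES))


def _adapt_focus(
    config: FitConfig, table: TruthTable, rng: np.random.Generator
) -> Dict[str, Tuple[float, float, float]]:
    """Cross-entropy refinement of the importance proposal's focus windows.

    The admissible q/w region is a rare event under the uniform prior, so
    the proposal is adapted at run time: starting from the structural
    windows in ``IMPORTANCE_FOCUS``, each iteration draws a pilot batch,
    ranks samples by Φ^C + Φ^H (with pruning at the current elite level γ),
    and moves each parameter's focus window to the elite quantiles, keeping
    a uniform mixture floor over the full range so the proposal's support —
    and hence the exactness of the final importance weights — is preserved.
    γ shrinks toward τ across iterations.  Only the q/w proposal adapts;
    the epigenetic draws always follow the study's Normal(mean, mean/10)
    law and are never tuned.
    """
    focus: Dict[str, Tuple[float, float, float]] = dict(IMPORTANCE_FOCUS)
    gamma = 0.6
    # Rank pilot samples at the nominal epigenetic values: the ranking then
    # reflects intrinsic q/w quality instead of per-draw epigenetic luck,
    # which would otherwise dominate the elite set and stall the shrinkage.
    log_hC = np.log(config.nominal_vector(ChromatinState.C))[None, :]
    log_hH = np.log(config.nominal_vector(ChromatinState.H))[None, :]
    n = config.adapt_samples
    for _ in range(config.adapt_iters):
        qw, _ = _sample_qw_weighted(config, n, rng, focus)
        log_q = np.log(qw[:, : len(Q_NAMES)])
        log_w = np.log(qw[:, len(Q_NAMES) :])
        phi_C, alive_C = engine.phi_column_pruned(
            log_q,
            log_w,
            np.broadcast_to(log_hC, (n, log_hC.shape[1])),
            config.residual,
            table,
            ChromatinState.C,
            gamma,
        )
        # Pruned samples carry their partial Φ^C plus a γ penalty so every
        # fully-evaluated sample ranks ahead of every pruned one.
        score = phi_C + gamma
        idx = np.where(alive_C)[0]
        if idx.size:
            phi_H, _ = engine.phi_column_pruned(
                log_q[idx],
                log_w[idx],
                np.broadcast_to(log_hH, (idx.size, log_hH.shape[1])),
                config.residual,
                table,
                ChromatinState.H,
                gamma,
            )
            score[idx] = phi_C[idx] + phi_H
        elite = np.argsort(score)[: config.adapt_elite]
        for i, name in enumerate(_QW_NAMES):
            lo, hi = config.ranges[name]
            flo, fhi = np.quantile(qw[elite, i], [0.02, 0.98])
            min_width = 0.01 * (hi - lo)
            if fhi - flo < min_width:
                mid = 0.5 * (flo + fhi)
                flo, fhi = mid - 0.5 * min_width, mid + 0.5 * min_width
            focus[name] = (0.85, max(lo, flo), min(hi, fhi))
        gamma = max(config.tau, float(np.quantile(score[elite], 0.8)))
    return focus


def run_fit(config: FitConfig, table: TruthTable) -> FitEnsemble:
    """Run the staged random search against a truth table.

    Batches of q/w draws (with h draws around the nominal C and H values)
    are filtered by Φ^C < τ then Φ^H < τ — both with exact early pruning, so
    clearly failing samples do not pay for all 16 rows; survivors get
    N-column h draws with the monotone trend enforced on the H→N leg, full
    Φ^N and 48-condition feasibility flags.  Stops after ``total_samples``
    raw draws, or earlier once ``target_retained`` samples survive the C/H
    filter.  Bit-reproducible for a fixed config.

    Returns a structured empty ensemble (with diagnostics) when nothing
    survives the filter.
    """
    rng = np.random.default_rng(config.seed)
    tau = config.tau
    nominal = {s: config.nominal_vector(s) for s in ChromatinState}
    focus = None
    if config.sampling == "importance" and config.adapt_proposal:
        focus = _adapt_focus(config, table, rng)

    frames: List[pd.DataFrame] = []
    h_parts: Dict[str, List[np.ndarray]] = {"C": [], "H": [], "N": []}
    n_sampled = 0
    n_retained = 0
    n_feasible_ch = 0
    n_feasible_all = 0

    while n_sampled < config.total_samples and (
        config.target_retained is None or n_retained < config.target_retained
    ):
        batch = min(config.batch_size, config.total_samples - n_sampled)
        qw, logw = _sample_qw_weighted(config, batch, rng, focus)
        n_sampled += batch

        # Exact pre-gate: the polymerase gain caps every P_binding, so
        # samples whose gain cannot reach the strong-expression rows are
        # dropped before any state-space evaluation.
        gain = qw[:, Q_NAMES.index("qR")] * qw[:, len(Q_NAMES) + W_NAMES.index("wCR")]
        pre = (
            engine.phi_lower_bound_from_gain(gain, table, ChromatinState.C) < tau
        ) & (engine.phi_lower_bound_from_gain(gain, table, ChromatinState.H) < tau)
        if not pre.any():
            continue
        sub = np.where(pre)[0]
        log_q = np.log(qw[sub, : len(Q_NAMES)])
        log_w = np.log(qw[sub, len(Q_NAMES) :])
        m = sub.size

        def _make_provider(
            nominal_vec: np.ndarray,
            store: np.ndarray,
            ref_store: Optional[np.ndarray] = None,
            ref_map: Optional[np.ndarray] = None,
        ):
            """Lazy per-row h sampler writing its draws into ``store``.

            When ``ref_store`` is given (global C→H monotonicity), draws are
            rejection-ordered against the matching C-column realisation.
            """
            per_condition = store.ndim == 3

            def provider(row: int, idx: np.ndarray) -> np.ndarray:
                if per_condition:
                    if ref_store is not None:
                        ref = ref_store[ref_map[idx], row - 1]
                        draws = _draw_h_n_monotone(nominal_vec, ref, rng, config.h_rel_sd)
                    else:
                        draws = _gaussian_h(
                            nominal_vec, (idx.size, len(H_NAMES)), rng, config.h_rel_sd
                        )
                    store[idx, row - 1] = draws
                else:
                    draws = store[idx]
                return np.log(draws)

            return provider

        hC_store = np.empty(_h_shape(config, m))
        if hC_store.ndim == 2:
            hC_store[:] = _gaussian_h(nominal[ChromatinState.C], (m, len(H_NAMES)), rng, config.h_rel_sd)
        phi_C_sub, pass_C = engine.phi_column_pruned_h(
            log_q, log_w, config.residual, table, ChromatinState.C, tau,
            _make_provider(nominal[ChromatinState.C], hC_store),
        )
        if not pass_C.any():
            continue
        idx_c = np.where(pass_C)[0]
        hH_store = np.empty(_h_shape(config, idx_c.size))
        ref_store = hC_store if (config.enforce_monotonicity_global and hH_store.ndim == 3) else None
        if hH_store.ndim == 2:
            hH_draws = _gaussian_h(nominal[ChromatinState.H], (idx_c.size, len(H_NAMES)), rng, config.h_rel_sd)
            if config.enforce_monotonicity_global:
                hH_draws = _draw_h_n_monotone(
                    nominal[ChromatinState.H], hC_store[idx_c], rng, config.h_rel_sd
                )
            hH_store[:] = hH_draws
        phi_H_sub, pass_H = engine.phi_column_pruned_h(
            log_q[idx_c], log_w[idx_c], config.residual, table, ChromatinState.H, tau,
            _make_provider(nominal[ChromatinState.H], hH_store, ref_store, idx_c),
        )
        if not pass_H.any():
            continue

        keep_rel = idx_c[pass_H]  # indices within the pre-gated subset
        keep = sub[keep_rel]  # retained sample indices within the batch
        lq, lw = log_q[keep_rel], log_w[keep_rel]
        hCk = hC_store[keep_rel]
        hHk = hH_store[pass_H]
        hNk = _draw_h_n_monotone(nominal[ChromatinState.N], hHk, rng, config.h_rel_sd)

        pb_C = engine.column_pbinding(lq, lw, np.log(hCk), config.residual)
        pb_H = engine.column_pbinding(lq, lw, np.log(hHk), config.residual)
        pb_N = engine.column_pbinding(lq, lw, np.log(hNk), config.residual)
        phi_N = engine.phi_column(pb_N, table, ChromatinState.N)

        feas_C = engine.inside_all_column(pb_C, table, ChromatinState.C)
        feas_H = engine.inside_all_column(pb_H, table, ChromatinState.H)
        feas_N = engine.inside_all_column(pb_N, table, ChromatinState.N)
        feas_ch = feas_C & feas_H
        feas_all = feas_ch & feas_N

        data: Dict[str, np.ndarray] = {}
        for i, name in enumerate(_QW_NAMES):
            data[name] = qw[keep, i]
        for arr, state in ((hCk, "C"), (hHk, "H"), (hNk, "N")):
            summary = arr.mean(axis=1) if arr.ndim == 3 else arr
            for i, name in enumerate(H_NAMES):
                data[f"{name}_{state}"] = summary[:, i]
        data["log_weight"] = logw[keep]
        data["phi_C"] = phi_C_sub[keep_rel]
        data["phi_H"] = phi_H_sub[pass_H]
        data["phi_N"] = phi_N
        data["feasible_ch"] = feas_ch
        data["feasible_all"] = feas_all
        if config.keep_pbinding:
            for col, pb in (("C", pb_C), ("H", pb_H), ("N", pb_N)):
                for j in range(16):
                    data[f"pb_{col}{j + 1}"] = pb[:, j]
        frames.append(pd.DataFrame(data))
        for arr, state in ((hCk, "C"), (hHk, "H"), (hNk, "N")):
            h_parts[state].append(arr)
        n_retained += len(keep)
        n_feasible_ch += int(feas_ch.sum())
        n_feasible_all += int(feas_all.sum())

    if frames:
        samples = pd.concat(frames, ignore_index=True)
        h_draws = {state: np.concatenate(parts) for state, parts in h_parts.items()}
    else:
        samples = pd.DataFrame(
            columns=list(_QW_NAMES) + ["phi_C", "phi_H", "phi_N", "feasible_ch", "feasible_all"]
        )
        h_draws = {state: np.empty((0,) + _h_shape(config, 1)[1:]) for state in ("C", "H", "N")}
    diagnostics = {
        "retained_fraction": n_retained / n_sampled if n_sampled else math.nan,
        "tau": config.tau,
        "seed": config.seed,
    }
    return FitEnsemble(
        samples=samples,
        n_sampled=n_sampled,
        n_retained=n_retained,
        n_feasible_ch=n_feasible_ch,
        n_feasible_all=n_feasible_all,
        config=config,
        h_draws=h_draws,
        diagnostics=diagnostics,
    )


def _column_pass_fraction(
    qw: np.ndarray,
    nominal_vec: np.ndarray,
    table: TruthTable,
    chromatin: ChromatinState,
    config: FitConfig,
    rng: np.random.Generator,
) -> float:
    """Fraction of a fixed q/w set passing one column's Φ filter with h drawn
    around a candidate nominal vector."""
    n = qw.shape[0]
    draws = _gaussian_h(nominal_vec, _h_shape(config, n), rng, config.h_rel_sd)
    _, alive = engine.phi_column_pruned(
        np.log(qw[:, : len(Q_NAMES)]),
        np.log(qw[:, len(Q_NAMES) :]),
        np.log(draws),
        config.residual,
        table,
        chromatin,
        config.tau,
    )
    return float(alive.mean())


def revalidate_n_column(
    ensemble: FitEnsemble,
    nominal_hN: EpigeneticFactors,
    table: TruthTable,
    seed: int = 0,
) -> FitEnsemble:
    """Re-run the N-column stage of a fitted ensemble with new nominal values.

    Keeps the retained q/w samples and their C/H epigenetic realisations and
    costs; redraws the N-column epigenetic factors around ``nominal_hN``
    (monotone H→N leg enforced per sample), recomputes Φ^N and the full
    48-condition feasibility, and returns a new ensemble.  This is the
    validation protocol: binding and interaction parameters stay fixed, only
    the epigenetic background is allowed to shift with chromatin state.
    """
    if ensemble.n_retained == 0:
        return ensemble
    config = ensemble.config
    rng = np.random.default_rng(seed)
    samples = ensemble.samples.copy()
    lq = np.log(samples[list(Q_NAMES)].to_numpy())
    lw = np.log(samples[list(W_NAMES)].to_numpy())
    nominal_vec = np.array([getattr(nominal_hN, name) for name in H_NAMES])
    hH = ensemble.h_draws["H"]
    hN = _draw_h_n_monotone(nominal_vec, hH, rng, config.h_rel_sd)
    pb_N = engine.column_pbinding(lq, lw, np.log(hN), config.residual)
    phi_N = engine.phi_column(pb_N, table, ChromatinState.N)
    feas_N = engine.inside_all_column(pb_N, table, ChromatinState.N)
    feas_all = samples["feasible_ch"].to_numpy(dtype=bool) & feas_N

    samples["phi_N"] = phi_N
    samples["feasible_all"] = feas_all
    summary = hN.mean(axis=1) if hN.ndim == 3 else hN
    for i, name in enumerate(H_NAMES):
        samples[f"{name}_N"] = summary[:, i]
    if config.keep_pbinding:
        for j in range(16):
            samples[f"pb_N{j + 1}"] = pb_N[:, j]
    h_draws = dict(ensemble.h_draws)
    h_draws["N"] = hN
    return FitEnsemble(
        samples=samples,
        n_sampled=ensemble.n_sampled,
        n_retained=ensemble.n_retained,
        n_feasible_ch=ensemble.n_feasible_ch,
        n_feasible_all=int(feas_all.sum()),
        config=config,
        h_draws=h_draws,
        diagnostics={**ensemble.diagnostics, "n_revalidation_seed": float(seed)},
    )


def tune_h(
    config: FitConfig,
    table: TruthTable,
    stage: ChromatinState = ChromatinState.N,
    n_eval_samples: int = 20_000,
    n_iters: int = 40,
    step_sd: float = 0.3,
    eval_qw: Optional[np.ndarray] = None,
) -> Tuple[EpigeneticFactors, Dict[str, float]]:
    """Random search over the *nominal* h values of one column.

    Formalises iterative manual retuning of the epigenetic nominals as a
    seeded multiplicative random walk: candidates are log-normal
    perturbations of the incumbent, scored by the fraction of a fixed q/w
    evaluation set passing the target column's Φ filter.  For stage N,
    candidates violating the monotone C→H→N trend of the nominals are
    rejected and counted.  Returns the best nominal found and a diagnostics
    dict; if no candidate improves on the input nominal, the input is
    returned unchanged.

    ``eval_qw`` supplies the q/w evaluation set explicitly — pass the
    retained samples of a C/H fit to retune the N column for exactly the
    parameter sets that survived calibration, which is how the validation
    stage is meant to be run; otherwise a fresh prior sample is drawn.
    """
    if stage == ChromatinState.C:
        raise ValueError("stage must be H or N; the C nominals anchor the search")
    rng = np.random.default_rng(config.seed)
    qw = eval_qw if eval_qw is not None else sample_qw_arrays(config, n_eval_samples, rng)

    incumbent = config.nominal_vector(stage)
    score_rng = np.random.default_rng(config.seed + 1)
    best_score = _column_pass_fraction(qw, incumbent, table, stage, config, score_rng)
    initial_score = best_score
    best = incumbent.copy()

    hC_nominal = config.nominal(ChromatinState.C)
    hH_nominal = config.nominal(ChromatinState.H)

    def monotone_ok(candidate: np.ndarray) -> bool:
        if stage == ChromatinState.H:
            return True
        hN = EpigeneticFactors(**dict(zip(H_NAMES, candidate)))
        return check_h_monotonicity(hC_nominal, hH_nominal, hN)

    n_rejected_monotone = 0
    for _ in range(n_iters):
        candidate = best * np.exp(rng.normal(0.0, step_sd, len(H_NAMES)))
        if not monotone_ok(candidate):
            n_rejected_monotone += 1
            continue
        score = _column_pass_fraction(qw, candidate, table, stage, config, score_rng)
        if score > best_score:
            best_score = score
            best = candidate
    diagnostics = {
        "initial_score": initial_score,
        "best_score": best_score,
        "improved": float(best_score > initial_score),
        "rejected_monotone": float(n_rejected_monotone),
    }
    return EpigeneticFactors(**dict(zip(H_NAMES, best))), diagnostics
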