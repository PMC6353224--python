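"""Synthetic truth tables with known ground truth, for end-to-end validation.

A synthetic table mirrors the structure of the experimental design — one
[lower, upper] expression interval per (mutation pattern, chromatin state)
condition — but is generated by pushing a known parameter set through the
forward model: each condition's interval is centred on its predicted
RNAp-binding probability and extends ±δ (clipped to [0, 1]).  The ground
truth is therefore feasible on its own table by construction, which makes
every stage of the fitting pipeline testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .fitting import FitConfig, FitEnsemble, phi, run_fit
from .params import (
    BindingAffinities,
    ChromatinState,
    DEFAULT_RESIDUAL,
    EpigeneticFactors,
    H_NAMES,
    InteractionFactors,
    ParameterSet,
    Q_NAMES,
    W_NAMES,
)
from .truth_table import (
    ExperimentCondition,
    ExpressionInterval,
    TruthTable,
    all_conditions,
    condition_pbinding,
)

__all__ = [
    "SyntheticSpec",
    "RecoveryReport",
    "default_ground_truth",
    "generate_truth_table",
    "recovery_experiment",
]


def default_ground_truth() -> ParameterSet:
    """A fixed, documented ground-truth parameterisation inside the sampling ranges.

    Chosen once as a biologically plausible operating point that produces
    graded expression across the design, mirroring the structure of the
    experimental table: near-maximal polymerase gain qR·wCR (strong
    expression is impossible otherwise), a mid-range Fer1 affinity qC, an
    asymmetric split of the two-domain TF affinities (Acj6 Homeobox-heavy,
    Pdm3 Pou-heavy, with effective double-binding qA ≪ qB), and the shipped
    nominal epigenetic values.
    """
    return ParameterSet(
        affinities=BindingAffinities(
            qR=0.028, qA1=2000.0, qA2=0.5, qB1=2.0, qB2=1200.0, qC=500.0
        ),
        interactions=InteractionFactors(
            wA1A2=60.0, wB1B2=80.0, wA1B2=0.0005, wB1A2=0.0005, wCR=85.0
        ),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a synthetic truth table.

    ``interval_half_width`` (δ) sets the interval [max(0, p−δ), min(1, p+δ)]
    around each forward-model value p.  ``center_jitter`` optionally shifts
    interval centres by Uniform(−jitter, +jitter) before clipping, emulating
    replicate-to-replicate drift; it is off by default because the
    experimental intervals encode replicate spread, not a known noise law.
    """

    ground_truth: ParameterSet = field(default_factory=default_ground_truth)
    interval_half_width: float = 0.1
    seed: int = 0
    rows: Optional[Sequence[int]] = None  # restrict to a mutation-pattern subset
    residual: float = DEFAULT_RESIDUAL
    center_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.interval_half_width <= 0.5:
            raise ValueError("interval_half_width must lie in (0, 0.5]")


def generate_truth_table(spec: SyntheticSpec) -> TruthTable:
    """Forward-simulate a truth table from the ground truth.

    Conditions outside ``spec.rows`` (when given) receive the maximal
    interval [0, 1], mirroring how missing experiments are encoded.
    """
    rng = np.random.default_rng(spec.seed)
    delta = spec.interval_half_width
    cells: Dict[Tuple[int, ChromatinState], ExpressionInterval] = {}
    for condition in all_conditions():
        if spec.rows is not None and condition.row not in spec.rows:
            cells[(condition.row, condition.chromatin)] = ExpressionInterval(0.0, 1.0)
            continue
        p = condition_pbinding(spec.ground_truth, condition, residual=spec.residual)
        center = p
        if spec.center_jitter > 0:
            center = p + rng.uniform(-spec.center_jitter, spec.center_jitter)
        # The ground-truth value stays inside the cell even when jitter
        # shifts the centre.
        lo = max(0.0, min(center - delta, p))
        hi = min(1.0, max(center + delta, p))
        cells[(condition.row, condition.chromatin)] = ExpressionInterval(lo, hi)
    return TruthTable(cells)


@dataclass
class RecoveryReport:
    """Outcome of a parameter-recovery experiment on a synthetic table."""

    spec: SyntheticSpec
    ensemble: FitEnsemble
    ground_truth_phi: float
    ground_truth_feasible: bool
    feasible_fraction: float  # feasible / retained
    marginals: Dict[str, Dict[str, float]]  # per q/w parameter

    def to_dict(self) -> Dict:
        return {
            "delta": self.spec.interval_half_width,
            "seed": self.spec.seed,
            "n_sampled": self.ensemble.n_sampled,
            "n_retained": self.ensemble.n_retained,
            "n_feasible": int(self.ensemble.n_feasible_all),
            "ground_truth_phi": self.ground_truth_phi,
            "ground_truth_feasible": self.ground_truth_feasible,
            "feasible_fraction": self.feasible_fraction,
            "marginals": self.marginals,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def recovery_experiment(spec: SyntheticSpec, fit_config: FitConfig) -> RecoveryReport:
    """Fit the synthetic table and report how well the truth is recovered.

    Reports Φ(ground truth) (exactly 0 by construction), the feasible
    fraction among retained samples, and — per q/w parameter — the feasible
    ensemble's marginal summary (min/max/IQR) next to its prior range,
    including whether the marginal covers the ground-truth value.
    """
    table = generate_truth_table(spec)
    gt_phi = phi(spec.ground_truth, table, residual=spec.residual)
    ensemble = run_fit(fit_config, table)

    marginals: Dict[str, Dict[str, float]] = {}
    feasible = ensemble.feasible
    truth_flat = {**spec.ground_truth.affinities.as_dict(), **spec.ground_truth.interactions.as_dict()}
    for name in Q_NAMES + W_NAMES:
        lo, hi = fit_config.ranges[name]
        entry: Dict[str, float] = {"prior_lo": lo, "prior_hi": hi, "truth": truth_flat[name]}
        if len(feasible):
            values = feasible[name].to_numpy()
            q1, q3 = np.percentile(values, [25, 75])
            entry.update(
                {
                    "feasible_min": float(values.min()),
                    "feasible_max": float(values.max()),
                    "feasible_iqr": float(q3 - q1),
                    "prior_iqr": 0.5 * (hi - lo),
                    "covered": bool(values.min() <= truth_flat[name] <= values.max()),
                }
            )
        marginals[name] = entry

    feasible_fraction = (
        ensemble.n_feasible_all / ensemble.n_retained if ensemble.n_retained else float("nan")
    )
    return RecoveryReport(
        spec=spec,
        ensemble=ensemble,
        ground_truth_phi=gt_phi,
        ground_truth_feasible=gt_phi == 0.0,
        feasible_fraction=feasible_fraction,
        marginals=marginals,
    )
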