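"""Ensemble-level analysis of the feasible parameter samples.

Summarises a fitted ensemble the way the method's results are read: the
distribution of the predicted RNAp-binding probability per experimental
condition, the distribution of the 48 state probabilities P(σ_k) per
condition, the dominant "on" state (largest ensemble-mean probability among
RNAp-bound states) and dominant "off" state (among RNAp-free states), and
marginal/correlation summaries of the feasible q/w parameter values against
their prior ranges.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import engine
from .fitting import FitEnsemble
from .params import ChromatinState, H_NAMES, Q_NAMES, W_NAMES
from .states import enumerate_states, rnap_bound_mask
from .truth_table import ExperimentCondition, TruthTable, all_conditions

__all__ = ["EnsembleSummary", "summarize_ensemble", "dominant_states", "export_summary"]

_QW = list(Q_NAMES + W_NAMES)
_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


class EmptyEnsembleError(RuntimeError):
    """Raised when a summary is requested for an ensemble with no feasible samples."""


def _select_subset(
    ensemble: FitEnsemble, subset: str = "feasible", n_best: int = 200
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Pick the samples a summary is computed over.

    ``subset="feasible"`` uses the exactly-feasible samples (Φ = 0 on all 48
    conditions) and raises :class:`EmptyEnsembleError` with stage counts when
    there are none.  ``subset="best"`` uses the ``n_best`` retained samples
    with the smallest Φ^C + Φ^H + Φ^N — the near-feasible ensemble, useful
    because exactly-feasible samples are rare under tight truth tables.
    """
    if ensemble.n_retained == 0:
        raise EmptyEnsembleError(
            f"empty ensemble: sampled={ensemble.n_sampled}, retained=0"
        )
    if subset == "feasible":
        mask = ensemble.feasible_mask
        if not mask.any():
            raise EmptyEnsembleError(
                "no feasible samples: "
                f"sampled={ensemble.n_sampled}, retained={ensemble.n_retained}, "
                f"feasible_ch={ensemble.n_feasible_ch}, feasible_all={ensemble.n_feasible_all}"
            )
    elif subset == "best":
        total = (
            ensemble.samples["phi_C"] + ensemble.samples["phi_H"] + ensemble.samples["phi_N"]
        ).to_numpy()
        order = np.argsort(total)[: min(n_best, total.size)]
        mask = np.zeros(total.size, dtype=bool)
        mask[order] = True
    else:
        raise ValueError("subset must be 'feasible' or 'best'")
    return ensemble.samples[mask], mask


def _subset_log_h(
    ensemble: FitEnsemble, chromatin: ChromatinState, mask: np.ndarray
) -> np.ndarray:
    """Log epigenetic draws of the selected samples for one column.

    Shape (n, 16, 5) for per-condition draws or (n, 5) for per-column draws.
    """
    return np.log(ensemble.h_draws[chromatin.value][mask])


def _state_probability_cube(
    ensemble: FitEnsemble, feasible: pd.DataFrame, mask: np.ndarray
) -> np.ndarray:
    """P(σ_k) for every selected sample × condition: shape (n, 48 cond, 48 states)."""
    log_q = np.log(feasible[list(Q_NAMES)].to_numpy())
    log_w = np.log(feasible[list(W_NAMES)].to_numpy())
    cube = np.empty((len(feasible), 48, 48))
    residual = ensemble.config.residual
    log_h = {s: _subset_log_h(ensemble, s, mask) for s in ChromatinState}
    for ci, condition in enumerate(all_conditions()):
        cube[:, ci, :] = engine.state_probabilities(
            log_q, log_w, log_h[condition.chromatin], residual, condition.row
        )
    return cube


@dataclass
class EnsembleSummary:
    """Summaries of the feasible ensemble (all frames indexed by condition code)."""

    pbinding: pd.DataFrame  # per condition: mean/std/quantiles of P_binding + bounds
    state_probability: pd.DataFrame  # per condition × state: mean/std of P(σ_k)
    dominant: pd.DataFrame  # per condition: on/off state index + occupancy
    parameter_marginals: pd.DataFrame  # per q/w parameter: prior range + quantiles
    parameter_correlations: pd.DataFrame  # q/w Pearson correlation matrix
    n_feasible: int

    def dominant_pair(self, condition: ExperimentCondition) -> Tuple[int, int]:
        row = self.dominant.loc[self.dominant["code"] == condition.code].iloc[0]
        return int(row["on_state"]), int(row["off_state"])


def summarize_ensemble(
    ensemble: FitEnsemble, table: TruthTable, subset: str = "feasible", n_best: int = 200
) -> EnsembleSummary:
    """Compute all ensemble summaries over the selected sample subset.

    By default only exactly-feasible samples enter (raising
    :class:`EmptyEnsembleError` with stage counts when there are none);
    ``subset="best"`` summarises the near-feasible ensemble instead.
    """
    feasible, mask = _select_subset(ensemble, subset, n_best)
    cube = _state_probability_cube(ensemble, feasible, mask)
    r_mask = rnap_bound_mask()
    states = enumerate_states()
    occupancy = {c.index: c.occupancy_description for c in states}

    pb_rows: List[Dict] = []
    sp_rows: List[Dict] = []
    dom_rows: List[Dict] = []
    for ci, condition in enumerate(all_conditions()):
        probs = cube[:, ci, :]  # (n, 48)
        pb = probs[:, r_mask].sum(axis=1)
        interval = table.interval(condition)
        entry = {
            "code": condition.code,
            "row": condition.row,
            "chromatin": condition.chromatin.value,
            "lower": interval.lower,
            "upper": interval.upper,
            "mean": pb.mean(),
            "std": pb.std(ddof=0),
        }
        for q in _QUANTILES:
            entry[f"q{int(q * 100):02d}"] = float(np.quantile(pb, q))
        pb_rows.append(entry)

        mean_probs = probs.mean(axis=0)
        std_probs = probs.std(axis=0, ddof=0)
        for k in range(48):
            sp_rows.append(
                {
                    "code": condition.code,
                    "state": k + 1,
                    "occupancy": occupancy[k + 1],
                    "rnap_bound": bool(r_mask[k]),
                    "mean": mean_probs[k],
                    "std": std_probs[k],
                }
            )

        on_idx, off_idx = _dominant_from_means(mean_probs, r_mask)
        dom_rows.append(
            {
                "code": condition.code,
                "on_state": on_idx,
                "on_occupancy": occupancy[on_idx],
                "on_mean_prob": mean_probs[on_idx - 1],
                "off_state": off_idx,
                "off_occupancy": occupancy[off_idx],
                "off_mean_prob": mean_probs[off_idx - 1],
            }
        )

    marg_rows = []
    for name in _QW:
        values = feasible[name].to_numpy()
        lo, hi = ensemble.config.ranges[name]
        entry = {
            "parameter": name,
            "prior_lo": lo,
            "prior_hi": hi,
            "mean": values.mean(),
            "std": values.std(ddof=0),
            "min": values.min(),
            "max": values.max(),
        }
        for q in _QUANTILES:
            entry[f"q{int(q * 100):02d}"] = float(np.quantile(values, q))
        marg_rows.append(entry)

    correlations = feasible[_QW].corr(method="pearson")

    return EnsembleSummary(
        pbinding=pd.DataFrame(pb_rows),
        state_probability=pd.DataFrame(sp_rows),
        dominant=pd.DataFrame(dom_rows),
        parameter_marginals=pd.DataFrame(marg_rows),
        parameter_correlations=correlations,
        n_feasible=len(feasible),
    )


def _dominant_from_means(mean_probs: np.ndarray, r_mask: np.ndarray) -> Tuple[int, int]:
    """Argmax state (1-based canonical index) over RNAp-bound and RNAp-free
    states; np.argmax's first-hit rule implements the lowest-index tie-break."""
    on = int(np.flatnonzero(r_mask)[np.argmax(mean_probs[r_mask])]) + 1
    off = int(np.flatnonzero(~r_mask)[np.argmax(mean_probs[~r_mask])]) + 1
    return on, off


def dominant_states(
    ensemble: FitEnsemble,
    condition: ExperimentCondition,
    subset: str = "feasible",
    n_best: int = 200,
) -> Tuple[int, int]:
    """Dominant (on, off) canonical state indices for one condition.

    "On" is the RNAp-bound state with the largest ensemble-mean probability
    over the selected samples; "off" the analogue among RNAp-free states.
    Ties break to the lowest canonical index.
    """
    feasible, mask = _select_subset(ensemble, subset, n_best)
    log_q = np.log(feasible[list(Q_NAMES)].to_numpy())
    log_w = np.log(feasible[list(W_NAMES)].to_numpy())
    log_h = _subset_log_h(ensemble, condition.chromatin, mask)
    probs = engine.state_probabilities(
        log_q, log_w, log_h, ensemble.config.residual, condition.row
    )
    return _dominant_from_means(probs.mean(axis=0), rnap_bound_mask())


def export_summary(
    summary: EnsembleSummary,
    out_dir,
    plots: bool = False,
    manifest_extra: Optional[Dict] = None,
) -> List[Path]:
    """Write the summary as CSV tables (plus optional PNG plots) to a directory.

    Returns the list of files written.  The JSON manifest records the
    feasible-sample count and a hash of the exported tables so a rerun can be
    compared at a glance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    tables = {
        "pbinding_summary.csv": summary.pbinding,
        "state_probability_summary.csv": summary.state_probability,
        "dominant_states.csv": summary.dominant,
        "parameter_marginals.csv": summary.parameter_marginals,
        "parameter_correlations.csv": summary.parameter_correlations,
    }
    digest = hashlib.sha256()
    for name, frame in tables.items():
        path = out / name
        frame.to_csv(path, index=(name == "parameter_correlations.csv"))
        digest.update(path.read_bytes())
        written.append(path)

    if plots:
        written.extend(_write_plots(summary, out))

    manifest = {
        "n_feasible": summary.n_feasible,
        "tables": sorted(tables),
        "sha256": digest.hexdigest(),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    written.append(manifest_path)
    return written


def _write_plots(summary: EnsembleSummary, out: Path) -> List[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: List[Path] = []
    fig, axes = plt.subplots(1, 3, figsize=(14, 4), sharey=True)
    for ax, state in zip(axes, ("C", "H", "N")):
        sub = summary.pbinding[summary.pbinding["chromatin"] == state]
        ax.errorbar(
            sub["row"],
            sub["mean"],
            yerr=sub["std"],
            fmt="o",
            label="ensemble mean ± sd",
        )
        ax.vlines(sub["row"], sub["lower"], sub["upper"], color="k", alpha=0.4, label="interval")
        ax.set_title(f"chromatin {state}")
        ax.set_xlabel("truth-table row")
    axes[0].set_ylabel("P_binding")
    handles, labels = axes[0].get_legend_handles_labels()
    fig.legend(handles[:2], labels[:2], loc="upper right")
    fig.tight_layout()
    path = out / "pbinding_summary.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
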