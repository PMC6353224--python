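"""Vectorised batch evaluation of P_binding over samples and conditions.

The random-search fit evaluates the model for ~10^5–10^7 parameter samples ×
48 experimental conditions, so the scalar path in :mod:`orthermo.states` is
far too slow.  This module evaluates whole sample batches with matrix
algebra: log-weights of the 48 states are linear in the log-parameters
(``log p = Q·log q + W·log w + H·log h`` with 0/1 exponent matrices), and a
site mutation is a rank-one update replacing one log-affinity column by the
log residual affinity.

The exponent matrices are built from :func:`orthermo.states.active_factors`,
so this path and the scalar path share one definition of the model.

Epigenetic draws may be supplied per sample (shape ``(n, 5)``) or per sample
× truth-table row (shape ``(n, 16, 5)``); the latter models independent
epigenetic realisations for the separately raised fly cohorts behind each
cell of the truth table.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .params import ChromatinState, Q_NAMES
from .states import factor_exponent_matrices, rnap_bound_mask
from .truth_table import TruthTable, mutation_pattern

__all__ = [
    "mutated_q_columns",
    "column_pbinding",
    "phi_column_pruned",
    "phi_column_pruned_h",
    "phi_lower_bound_from_gain",
    "state_probabilities",
    "phi_column",
    "inside_all_column",
]

_QA1, _QA2, _QB1, _QB2, _QC = (Q_NAMES.index(n) for n in ("qA1", "qA2", "qB1", "qB2", "qC"))

# Row evaluation order for pruned Φ computation: most selective first (the
# strong-expression and boundary-straddling rows reject the bulk of uniform
# draws), so pruned samples skip the remaining rows.  Any order is exact.
_PRUNE_ORDER: Tuple[int, ...] = (12, 8, 16, 4, 10, 14, 2, 6, 1, 3, 5, 7, 9, 11, 13, 15)


def mutated_q_columns(row: int) -> List[int]:
    """Indices (into ``Q_NAMES``) of affinities replaced by the residual in row E{row}."""
    acj6hox, pdm3hox, pou, ebox = mutation_pattern(row)
    cols: List[int] = []
    if acj6hox == 0:
        cols.append(_QA1)
    if pdm3hox == 0:
        cols.append(_QB1)
    if pou == 0:
        cols.extend([_QA2, _QB2])
    if ebox == 0:
        cols.append(_QC)
    return cols


def _row_log_h(log_h: np.ndarray, row: int) -> np.ndarray:
    """Per-sample log-h slice for one truth-table row (shared or per-row)."""
    if log_h.ndim == 3:
        return log_h[:, row - 1, :]
    return log_h


def _row_pbinding(
    base_qw: np.ndarray,
    log_q: np.ndarray,
    log_h: np.ndarray,
    H_T: np.ndarray,
    Q: np.ndarray,
    r_mask: np.ndarray,
    log_res: float,
    row: int,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """P_binding of one truth-table row for all samples (or a subset)."""
    if subset is not None:
        base = base_qw[subset]
        lq = log_q[subset]
        lh = _row_log_h(log_h, row)[subset]
    else:
        base = base_qw
        lq = log_q
        lh = _row_log_h(log_h, row)
    L = base + lh @ H_T
    cols = mutated_q_columns(row)
    if cols:
        L += (log_res - lq[:, cols]) @ Q[:, cols].T
    L -= L.max(axis=1, keepdims=True)
    E = np.exp(L)
    return E[:, r_mask].sum(axis=1) / E.sum(axis=1)


def column_pbinding(
    log_q: np.ndarray,
    log_w: np.ndarray,
    log_h: np.ndarray,
    residual: float,
    rows: Sequence[int] = tuple(range(1, 17)),
) -> np.ndarray:
    """P_binding for every sample × truth-table row in one chromatin column.

    Parameters
    ----------
    log_q, log_w
        Arrays of shape (n, 6) and (n, 5): per-sample log parameters in the
        canonical ``Q_NAMES`` / ``W_NAMES`` order.
    log_h
        Per-sample epigenetic log-draws for this chromatin column: shape
        (n, 5) for one shared draw per sample, or (n, 16, 5) for one draw
        per sample and truth-table row.
    residual
        Residual affinity substituted for mutated motifs.
    rows
        Truth-table rows to evaluate (default all 16).

    Returns
    -------
    ndarray of shape (n, len(rows)) of RNAp-binding probabilities.
    """
    Q, W, H = factor_exponent_matrices()
    r_mask = rnap_bound_mask()
    base_qw = log_q @ Q.T + log_w @ W.T  # (n, 48)
    out = np.empty((base_qw.shape[0], len(rows)))
    for j, row in enumerate(rows):
        out[:, j] = _row_pbinding(
            base_qw, log_q, log_h, H.T, Q, r_mask, np.log(residual), row
        )
    return out


def phi_column_pruned(
    log_q: np.ndarray,
    log_w: np.ndarray,
    log_h: np.ndarray,
    residual: float,
    table: TruthTable,
    chromatin: ChromatinState,
    tau: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Column cost Φ with exact early pruning at threshold τ.

    Because Φ is a sum of nonnegative per-row distances, a sample whose
    partial sum already reaches τ cannot fall below it; such samples skip
    the remaining rows.  Rows are visited most-selective-first.

    Returns
    -------
    (phi, alive) where ``alive`` marks samples with Φ < τ; for those, ``phi``
    is exact.  For pruned samples ``phi`` holds the partial sum at pruning
    time (a valid lower bound ≥ τ).
    """
    Q, W, H = factor_exponent_matrices()
    r_mask = rnap_bound_mask()
    n = log_q.shape[0]
    base_qw = log_q @ Q.T + log_w @ W.T
    phi = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    log_res = np.log(residual)
    for row in _PRUNE_ORDER:
        if not alive.any():
            break
        idx = np.where(alive)[0]
        pb = _row_pbinding(base_qw, log_q, log_h, H.T, Q, r_mask, log_res, row, subset=idx)
        interval = table[(row, chromatin)]
        d = np.maximum(interval.lower - pb, 0.0) + np.maximum(pb - interval.upper, 0.0)
        phi[idx] += d
        alive[idx] = phi[idx] < tau
    return phi, alive


def phi_lower_bound_from_gain(
    qR_wCR: np.ndarray, table: TruthTable, chromatin: ChromatinState
) -> np.ndarray:
    """Exact per-sample lower bound on a column's Φ from the polymerase gain.

    Every RNAp-bound state is its RNAp-free mirror times qR (times wCR when
    Fer1 co-recruits), so P_binding ≤ qR·wCR/(1 + qR·wCR) for every
    condition.  Summing each row's unreachable shortfall below its lower
    bound gives a valid lower bound on Φ, usable as a cheap pre-filter
    before any state-space work.
    """
    cap = qR_wCR / (1.0 + qR_wCR)
    lo = np.array([table[(row, chromatin)].lower for row in range(1, 17)])
    return np.clip(lo[None, :] - cap[:, None], 0.0, None).sum(axis=1)


def phi_column_pruned_h(
    log_q: np.ndarray,
    log_w: np.ndarray,
    residual: float,
    table: TruthTable,
    chromatin: ChromatinState,
    tau: float,
    h_provider,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pruned column cost Φ with epigenetic draws supplied lazily per row.

    ``h_provider(row, idx)`` returns the (len(idx), 5) *log* epigenetic
    values for the still-alive sample subset ``idx`` at truth-table row
    ``row``; it is called once per visited row, so epigenetic realisations
    are only ever drawn for samples that still matter.  Inner exponentials
    run in float32 — distances live on the 0.01–1 scale, far above float32
    resolution.  Semantics otherwise as :func:`phi_column_pruned`.
    """
    Q, W, H = factor_exponent_matrices()
    r_mask = rnap_bound_mask()
    n = log_q.shape[0]
    base_qw = (log_q @ Q.T + log_w @ W.T).astype(np.float32)
    H_T32 = H.T.astype(np.float32)
    phi = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    log_res = np.log(residual)
    for row in _PRUNE_ORDER:
        if not alive.any():
            break
        idx = np.where(alive)[0]
        lh = h_provider(row, idx).astype(np.float32)
        L = base_qw[idx] + lh @ H_T32
        cols = mutated_q_columns(row)
        if cols:
            L += ((log_res - log_q[idx][:, cols]) @ Q[:, cols].T).astype(np.float32)
        L -= L.max(axis=1, keepdims=True)
        E = np.exp(L)
        pb = E[:, r_mask].sum(axis=1) / E.sum(axis=1)
        interval = table[(row, chromatin)]
        d = np.maximum(interval.lower - pb, 0.0) + np.maximum(pb - interval.upper, 0.0)
        phi[idx] += d
        alive[idx] = phi[idx] < tau
    return phi, alive


def state_probabilities(
    log_q: np.ndarray,
    log_w: np.ndarray,
    log_h: np.ndarray,
    residual: float,
    row: int,
) -> np.ndarray:
    """Normalised state probabilities P(σ_k) for one truth-table row.

    ``log_h`` may be (n, 5) or (n, 16, 5) as in :func:`column_pbinding`.
    Returns an (n, 48) array in canonical state order; each sample's row
    sums to 1 and its RNAp-bound mass equals that condition's P_binding.
    """
    Qm, Wm, Hm = factor_exponent_matrices()
    L = log_q @ Qm.T + log_w @ Wm.T + _row_log_h(log_h, row) @ Hm.T
    cols = mutated_q_columns(row)
    if cols:
        L = L + (np.log(residual) - log_q[:, cols]) @ Qm[:, cols].T
    L -= L.max(axis=1, keepdims=True)
    E = np.exp(L)
    return E / E.sum(axis=1, keepdims=True)


def _bounds(table: TruthTable, chromatin: ChromatinState) -> Dict[str, np.ndarray]:
    lo = np.array([table[(row, chromatin)].lower for row in range(1, 17)])
    hi = np.array([table[(row, chromatin)].upper for row in range(1, 17)])
    return {"lo": lo, "hi": hi}


def phi_column(pbinding: np.ndarray, table: TruthTable, chromatin: ChromatinState) -> np.ndarray:
    """Per-sample cost Φ for one column: summed set distances over its 16 rows."""
    b = _bounds(table, chromatin)
    d = np.maximum(b["lo"] - pbinding, 0.0) + np.maximum(pbinding - b["hi"], 0.0)
    return d.sum(axis=1)


def inside_all_column(pbinding: np.ndarray, table: TruthTable, chromatin: ChromatinState) -> np.ndarray:
    """Per-sample flag: P_binding inside the interval for all 16 rows of a column."""
    b = _bounds(table, chromatin)
    return np.all((pbinding >= b["lo"]) & (pbinding <= b["hi"]), axis=1)
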