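"""Enumeration of the 48 molecular configurations and their statistical weights.

A configuration σ_k is one joint occupancy assignment of the five DNA sites of
the enhancer cluster: the Acj6 Homeobox site (empty or A1), the Pdm3 Homeobox
site (empty or B1), the shared Pou site (empty, A2 or B2 — the two Pou domains
compete for a single site), the Ebox (empty or Fer1/C) and the TATA box (empty
or RNAp/R).  This gives 2·2·3·2·2 = 48 states.

Each state carries a statistical weight

    p_k = Π_j q_j · Π_jn w_jn · Π_m h_m

the product of the affinity ratios of its occupied sites, the interaction
factors of its co-bound pairs, and the epigenetic factors of the chromatin
background.  Normalising by the partition function Z_tot = Σ_k p_k gives the
state probabilities, and the model observable is the probability that RNAp
occupies the TATA box: the summed probability of the 24 R-bound states.

Canonical index convention
--------------------------
Indices 1–24 have the TATA box empty, 25–48 have RNAp bound (state k+24 is
state k plus RNAp).  Within each block of 24: offsets 1–12 have the Ebox
empty and 13–24 have Fer1 bound.  The within-block placement is frozen (see
``data/state_table.csv`` for the full mapping); the named landmarks include
σ6 = A1+B1, σ9 = B1+B2, σ13/σ37 = B1+B2+C(+R), σ14/σ38 = A1+A2+C(+R),
σ21/σ45 = C(+R) alone, σ24/σ48 = A1+B1+C(+R), σ41 = B2+C+R, σ42 = A2+C+R.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

from .params import (
    BindingAffinities,
    ChromatinState,
    EpigeneticFactors,
    H_NAMES,
    InteractionFactors,
    Q_NAMES,
    W_NAMES,
)

__all__ = [
    "Configuration",
    "ModelEvaluation",
    "enumerate_states",
    "active_factors",
    "state_weight",
    "evaluate",
    "rnap_bound_indices",
    "factor_exponent_matrices",
    "state_table_frame",
    "export_state_table",
]

EMPTY = "empty"

N_STATES = 48


@dataclass(frozen=True)
class Configuration:
    """One molecular state σ_k: joint occupancy of the five cluster sites."""

    index: int  # canonical index in 1..48
    hoxA: str  # "empty" | "A1"
    hoxB: str  # "empty" | "B1"
    pou: str  # "empty" | "A2" | "B2"
    ebox: str  # "empty" | "C"
    tata: str  # "empty" | "R"

    def __post_init__(self) -> None:
        if self.hoxA not in (EMPTY, "A1"):
            raise ValueError(f"hoxA must be 'empty' or 'A1', got {self.hoxA!r}")
        if self.hoxB not in (EMPTY, "B1"):
            raise ValueError(f"hoxB must be 'empty' or 'B1', got {self.hoxB!r}")
        if self.pou not in (EMPTY, "A2", "B2"):
            raise ValueError(f"pou must be 'empty', 'A2' or 'B2', got {self.pou!r}")
        if self.ebox not in (EMPTY, "C"):
            raise ValueError(f"ebox must be 'empty' or 'C', got {self.ebox!r}")
        if self.tata not in (EMPTY, "R"):
            raise ValueError(f"tata must be 'empty' or 'R', got {self.tata!r}")

    @property
    def rnap_bound(self) -> bool:
        return self.tata == "R"

    @property
    def occupancy_description(self) -> str:
        """Human-readable ligand list, e.g. 'A1+A2+C+R'; 'empty' if bare DNA."""
        ligands = [x for x in (self.hoxA, self.hoxB, self.pou, self.ebox, self.tata) if x != EMPTY]
        return "+".join(ligands) if ligands else EMPTY

    @property
    def label(self) -> str:
        return f"sigma_{self.index}"


# Frozen within-block order of the 24 TATA-empty occupancies:
# (hoxA, hoxB, pou, ebox).  Offsets 1-12 Ebox empty (singles, pairs, triples);
# 13-24 Fer1 bound (double-bound + crossed Pou states, then C alone, then
# Pou-empty Homeobox states).
_BLOCK_OCCUPANCIES: Tuple[Tuple[str, str, str, str], ...] = (
    (EMPTY, EMPTY, EMPTY, EMPTY),  # 1: bare DNA
    ("A1", EMPTY, EMPTY, EMPTY),  # 2
    (EMPTY, EMPTY, "A2", EMPTY),  # 3
    (EMPTY, "B1", EMPTY, EMPTY),  # 4
    (EMPTY, EMPTY, "B2", EMPTY),  # 5
    ("A1", "B1", EMPTY, EMPTY),  # 6: both Homeobox sites
    ("A1", EMPTY, "A2", EMPTY),  # 7: Acj6 doubly bound
    ("A1", EMPTY, "B2", EMPTY),  # 8: crossed A1/B2
    (EMPTY, "B1", "B2", EMPTY),  # 9: Pdm3 doubly bound
    (EMPTY, "B1", "A2", EMPTY),  # 10: crossed B1/A2
    ("A1", "B1", "A2", EMPTY),  # 11
    ("A1", "B1", "B2", EMPTY),  # 12
    (EMPTY, "B1", "B2", "C"),  # 13: Pdm3 double + Fer1
    ("A1", EMPTY, "A2", "C"),  # 14: Acj6 double + Fer1
    ("A1", "B1", "A2", "C"),  # 15
    ("A1", "B1", "B2", "C"),  # 16
    (EMPTY, EMPTY, "B2", "C"),  # 17
    (EMPTY, EMPTY, "A2", "C"),  # 18
    ("A1", EMPTY, "B2", "C"),  # 19: crossed A1/B2 + Fer1
    (EMPTY, "B1", "A2", "C"),  # 20: crossed B1/A2 + Fer1
    (EMPTY, EMPTY, EMPTY, "C"),  # 21: Fer1 alone
    ("A1", EMPTY, EMPTY, "C"),  # 22
    (EMPTY, "B1", EMPTY, "C"),  # 23
    ("A1", "B1", EMPTY, "C"),  # 24
)


def enumerate_states() -> List[Configuration]:
    """All 48 configurations in the frozen canonical order (σ_1 … σ_48)."""
    states: List[Configuration] = []
    for tata in (EMPTY, "R"):
        base = 0 if tata == EMPTY else 24
        for offset, (hoxA, hoxB, pou, ebox) in enumerate(_BLOCK_OCCUPANCIES, start=1):
            states.append(
                Configuration(index=base + offset, hoxA=hoxA, hoxB=hoxB, pou=pou, ebox=ebox, tata=tata)
            )
    return states


def rnap_bound_indices() -> List[int]:
    """Canonical indices of the RNAp-bound states (25..48)."""
    return [c.index for c in enumerate_states() if c.rnap_bound]


def active_factors(config: Configuration, chromatin: ChromatinState | None = None) -> FrozenSet[str]:
    """Labels of every multiplicative factor active in a configuration.

    The chromatin state selects *which numeric values* the h labels take but
    not which labels apply, so it is accepted for interface symmetry and may
    be omitted.
    """
    labels: set[str] = set()
    a1 = config.hoxA == "A1"
    b1 = config.hoxB == "B1"
    a2 = config.pou == "A2"
    b2 = config.pou == "B2"
    c = config.ebox == "C"
    r = config.tata == "R"

    if a1:
        labels.add("qA1")
    if b1:
        labels.add("qB1")
    if a2:
        labels.add("qA2")
    if b2:
        labels.add("qB2")
    if c:
        labels.add("qC")
    if r:
        labels.add("qR")

    if a1 and a2:
        labels.add("wA1A2")
    if b1 and b2:
        labels.add("wB1B2")
    if a1 and b2:
        labels.add("wA1B2")
    if b1 and a2:
        labels.add("wB1A2")
    # Fer1–RNAp cooperativity requires Fer1 to be stabilised by at least one
    # other TF on the cluster: bare-Fer1 binding (the h1 configurations
    # σ21/σ45) is too transient to recruit RNAp.  Without this exception the
    # "only Ebox intact" experiment could not be a total-loss phenotype while
    # the Pdm3Hox-mutant experiment shows strong expression.
    if c and r and (a1 or b1 or a2 or b2):
        labels.add("wCR")

    if c:
        pou_occupied = a2 or b2
        if not (a1 or b1 or pou_occupied):
            labels.add("h1")
        if not pou_occupied and (a1 or b1):
            labels.add("h2")
        if pou_occupied:
            labels.add("h3")
        if a1 and a2:
            labels.add("hA")
        if b1 and b2:
            labels.add("hB")
    return frozenset(labels)


def state_weight(
    config: Configuration,
    affinities: BindingAffinities,
    interactions: InteractionFactors,
    epigenetics: EpigeneticFactors,
) -> float:
    """Statistical weight p_k: product of the active q, w and h factors.

    The all-empty configuration has weight 1 (empty product).  Computed as a
    sum of log factors to stay stable across the ~9 orders of magnitude the
    parameter ranges span.
    """
    values: Dict[str, float] = {}
    values.update(affinities.as_dict())
    values.update(interactions.as_dict())
    values.update(epigenetics.as_dict())
    log_w = 0.0
    for label in active_factors(config):
        log_w += np.log(values[label])
    return float(np.exp(log_w))


@dataclass(frozen=True)
class ModelEvaluation:
    """Weights, partition function, state probabilities and P_binding."""

    weights: np.ndarray  # shape (48,), p_k in canonical order
    Ztot: float
    probabilities: np.ndarray  # shape (48,), P(σ_k) = p_k / Z_tot
    pBinding: float  # Σ_{k: RNAp bound} P(σ_k)


# Cached exponent matrices mapping log-parameters to log-weights.
_EXPONENTS: Dict[str, np.ndarray] = {}


def factor_exponent_matrices() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponent matrices (Q, W, H) with log p = Q·log q + W·log w + H·log h.

    Q is (48, 6) over ``Q_NAMES``, W is (48, 5) over ``W_NAMES``, H is
    (48, 5) over ``H_NAMES``; entries are 0/1 multiplicities.  Built once
    from :func:`active_factors`, so the scalar and vectorised paths share a
    single source of truth.
    """
    if not _EXPONENTS:
        states = enumerate_states()
        Q = np.zeros((N_STATES, len(Q_NAMES)))
        W = np.zeros((N_STATES, len(W_NAMES)))
        H = np.zeros((N_STATES, len(H_NAMES)))
        for i, config in enumerate(states):
            for label in active_factors(config):
                if label in Q_NAMES:
                    Q[i, Q_NAMES.index(label)] = 1.0
                elif label in W_NAMES:
                    W[i, W_NAMES.index(label)] = 1.0
                else:
                    H[i, H_NAMES.index(label)] = 1.0
        _EXPONENTS["Q"] = Q
        _EXPONENTS["W"] = W
        _EXPONENTS["H"] = H
        _EXPONENTS["R"] = np.array([c.rnap_bound for c in states], dtype=bool)
    return _EXPONENTS["Q"], _EXPONENTS["W"], _EXPONENTS["H"]


def rnap_bound_mask() -> np.ndarray:
    """Boolean mask over the canonical order marking RNAp-bound states."""
    factor_exponent_matrices()
    return _EXPONENTS["R"]


def evaluate(
    affinities: BindingAffinities,
    interactions: InteractionFactors,
    epigenetics: EpigeneticFactors,
) -> ModelEvaluation:
    """Evaluate the thermodynamic model for one parameterisation.

    Returns the 48 statistical weights, the partition function, the
    normalised state probabilities and the RNAp-binding probability
    P_binding = Σ_{k=25..48} P(σ_k).  Probabilities are formed by shifting
    log-weights by their maximum before exponentiating, so extreme (but
    positive, finite) parameters cannot overflow the normalisation.
    """
    Q, W, H = factor_exponent_matrices()
    log_q = np.log([getattr(affinities, n) for n in Q_NAMES])
    log_w = np.log([getattr(interactions, n) for n in W_NAMES])
    log_h = np.log([getattr(epigenetics, n) for n in H_NAMES])
    log_weights = Q @ log_q + W @ log_w + H @ log_h
    shifted = np.exp(log_weights - log_weights.max())
    probabilities = shifted / shifted.sum()
    p_binding = float(probabilities[rnap_bound_mask()].sum())
    weights = np.exp(log_weights)
    return ModelEvaluation(
        weights=weights,
        Ztot=float(weights.sum()),
        probabilities=probabilities,
        pBinding=p_binding,
    )


def state_table_frame():
    """The canonical state table as a pandas DataFrame.

    Columns: index, hoxA, hoxB, pou, ebox, tata, occupancy, q_factors,
    w_factors, h_factors (factor lists are '+'-joined, '-' when none).
    """
    import pandas as pd

    rows = []
    for config in enumerate_states():
        labels = active_factors(config)
        q = sorted(l for l in labels if l in Q_NAMES)
        w = sorted(l for l in labels if l in W_NAMES)
        h = sorted(l for l in labels if l in H_NAMES)
        rows.append(
            {
                "index": config.index,
                "hoxA": config.hoxA,
                "hoxB": config.hoxB,
                "pou": config.pou,
                "ebox": config.ebox,
                "tata": config.tata,
                "occupancy": config.occupancy_description,
                "q_factors": "+".join(q) if q else "-",
                "w_factors": "+".join(w) if w else "-",
                "h_factors": "+".join(h) if h else "-",
            }
        )
    return pd.DataFrame(rows)


def export_state_table(path) -> None:
    """Write the canonical 48-row state table as CSV."""
    state_table_frame().to_csv(path, index=False)
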