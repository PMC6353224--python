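"""The 16×3 experimental design and its admissible expression intervals.

Each row E1..E16 is one mutation pattern of the four cluster binding motifs
(Acj6Hox, Pdm3Hox, Pou, Ebox; 0 = mutated, 1 = intact), enumerated in binary
order (E1 = 0000, E16 = 1111, most-significant bit Acj6Hox).  Each column is
one chromatin background (C, H, N).  A cell holds the interval [lower, upper]
of normalised cluster-driven expression compatible with experiment; missing
experiments carry the maximal interval [0, 1], and every Ebox-mutated row —
plus E2, where expression is always lost — carries [0, 0.1] ("total loss").

A mutated motif does not abolish binding outright: its affinity ratio is
replaced by a residual value several orders of magnitude below the functional
range (default 10^-5.5, within [1e-6, 1e-5]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterator, List, Tuple

import pandas as pd

from .params import (
    BindingAffinities,
    ChromatinState,
    DEFAULT_RESIDUAL,
    ParameterSet,
    RESIDUAL_RANGE,
)
from .states import evaluate

__all__ = [
    "MUTATION_SITES",
    "ExperimentCondition",
    "ExpressionInterval",
    "TruthTable",
    "mutation_pattern",
    "all_conditions",
    "default_truth_table",
    "apply_condition",
    "condition_pbinding",
]

MUTATION_SITES: Tuple[str, ...] = ("acj6hox", "pdm3hox", "pou", "ebox")

N_PATTERNS = 16


def mutation_pattern(row: int) -> Tuple[int, int, int, int]:
    """Binary mutation flags (acj6hox, pdm3hox, pou, ebox) for row E1..E16."""
    if not 1 <= row <= N_PATTERNS:
        raise ValueError(f"row must be in 1..16, got {row}")
    bits = format(row - 1, "04b")
    return tuple(int(b) for b in bits)  # type: ignore[return-value]


@dataclass(frozen=True)
class ExperimentCondition:
    """One condition θ: a mutation pattern plus a chromatin background."""

    row: int  # 1..16, labelling E1..E16
    chromatin: ChromatinState

    def __post_init__(self) -> None:
        if not 1 <= self.row <= N_PATTERNS:
            raise ValueError(f"row must be in 1..16, got {self.row}")

    @property
    def mutations(self) -> Tuple[int, int, int, int]:
        """(acj6hox, pdm3hox, pou, ebox); 0 = mutated, 1 = intact."""
        return mutation_pattern(self.row)

    @property
    def code(self) -> str:
        return f"E{self.chromatin.value}{self.row}"

    @property
    def ebox_mutated(self) -> bool:
        return self.mutations[3] == 0


def all_conditions() -> List[ExperimentCondition]:
    """All 48 conditions, rows E1..E16 within chromatin columns C, H, N."""
    return [
        ExperimentCondition(row=row, chromatin=state)
        for state in ChromatinState
        for row in range(1, N_PATTERNS + 1)
    ]


@dataclass(frozen=True)
class ExpressionInterval:
    """Admissible normalised-expression interval [lower, upper] ⊆ [0, 1]."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"require 0 <= lower <= upper <= 1, got [{self.lower}, {self.upper}]")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def distance(self, x: float) -> float:
        """Euclidean set distance of x from the interval."""
        return max(self.lower - x, x - self.upper, 0.0)


class TruthTable:
    """Map from (row, chromatin) conditions to expression intervals."""

    def __init__(self, cells: Dict[Tuple[int, ChromatinState], ExpressionInterval]):
        missing = {
            (c.row, c.chromatin) for c in all_conditions()
        } - set(cells)
        if missing:
            raise ValueError(f"truth table incomplete; missing cells {sorted_keys(missing)}")
        self._cells = dict(cells)

    def __getitem__(self, key: Tuple[int, ChromatinState]) -> ExpressionInterval:
        return self._cells[key]

    def interval(self, condition: ExperimentCondition) -> ExpressionInterval:
        return self._cells[(condition.row, condition.chromatin)]

    def __iter__(self) -> Iterator[Tuple[ExperimentCondition, ExpressionInterval]]:
        for condition in all_conditions():
            yield condition, self.interval(condition)

    def __len__(self) -> int:
        return len(self._cells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthTable):
            return NotImplemented
        return self._cells == other._cells

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame: code, mutation flags, chromatin, bounds."""
        rows = []
        for condition, interval in self:
            a, b, p, e = condition.mutations
            rows.append(
                {
                    "code": f"E{condition.row}",
                    "acj6hox": a,
                    "pdm3hox": b,
                    "pou": p,
                    "ebox": e,
                    "chromatin": condition.chromatin.value,
                    "lower": interval.lower,
                    "upper": interval.upper,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TruthTable":
        cells: Dict[Tuple[int, ChromatinState], ExpressionInterval] = {}
        for _, rec in frame.iterrows():
            row = int(str(rec["code"]).lstrip("E"))
            state = ChromatinState(rec["chromatin"])
            cells[(row, state)] = ExpressionInterval(float(rec["lower"]), float(rec["upper"]))
        return cls(cells)

    @classmethod
    def from_csv(cls, path) -> "TruthTable":
        return cls.from_frame(pd.read_csv(path))


def sorted_keys(keys):
    return sorted((row, state.value) for row, state in keys)


# Experimental intervals per row, columns (C, H, N).  Ebox-mutated rows (odd
# rows) and E2 are "total loss" [0, 0.1]; cells without an experiment are the
# maximal interval [0, 1].
_TOTAL_LOSS = ((0.0, 0.1), (0.0, 0.1), (0.0, 0.1))
_TABLE: Dict[int, Tuple[Tuple[float, float], ...]] = {
    1: _TOTAL_LOSS,
    2: _TOTAL_LOSS,
    3: _TOTAL_LOSS,
    4: ((0.2, 0.4), (0.0, 1.0), (0.2, 0.5)),
    5: _TOTAL_LOSS,
    6: ((0.0, 0.2), (0.0, 1.0), (0.0, 0.4)),
    7: _TOTAL_LOSS,
    8: ((0.4, 0.5), (0.0, 0.2), (0.0, 0.1)),
    9: _TOTAL_LOSS,
    10: ((0.1, 0.2), (0.0, 1.0), (0.0, 1.0)),
    11: _TOTAL_LOSS,
    12: ((0.6, 1.0), (0.6, 1.0), (0.6, 1.0)),
    13: _TOTAL_LOSS,
    14: ((0.0, 0.1), (0.0, 0.2), (0.1, 0.2)),
    15: _TOTAL_LOSS,
    16: ((0.1, 0.4), (0.0, 0.5), (0.4, 0.5)),
}


def default_truth_table() -> TruthTable:
    """The embedded experimental truth table (16 rows × 3 chromatin states)."""
    cells: Dict[Tuple[int, ChromatinState], ExpressionInterval] = {}
    for row, bounds in _TABLE.items():
        for state, (lo, hi) in zip(ChromatinState, bounds):
            cells[(row, state)] = ExpressionInterval(lo, hi)
    return TruthTable(cells)


def apply_condition(
    condition: ExperimentCondition,
    affinities: BindingAffinities,
    residual: float = DEFAULT_RESIDUAL,
    strict: bool = False,
) -> BindingAffinities:
    """Effective affinities under a mutation pattern.

    Each mutated motif's affinity ratio is replaced by the residual value:
    Acj6Hox → qA1, Pdm3Hox → qB1, Pou → both qA2 and qB2 (a single shared
    site serves both Pou domains), Ebox → qC.  qR is never altered — the
    TATA box is not part of the mutated cluster.
    """
    lo, hi = RESIDUAL_RANGE
    if not lo <= residual <= hi:
        msg = f"residual affinity {residual} outside the expected range [{lo}, {hi}]"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    acj6hox, pdm3hox, pou, ebox = condition.mutations
    updates: Dict[str, float] = {}
    if acj6hox == 0:
        updates["qA1"] = residual
    if pdm3hox == 0:
        updates["qB1"] = residual
    if pou == 0:
        updates["qA2"] = residual
        updates["qB2"] = residual
    if ebox == 0:
        updates["qC"] = residual
    return affinities.replace(**updates) if updates else affinities


def condition_pbinding(
    params: ParameterSet,
    condition: ExperimentCondition,
    residual: float = DEFAULT_RESIDUAL,
) -> float:
    """RNAp-binding probability for one experimental condition θ.

    Applies the mutation pattern to the affinities, selects the epigenetic
    factors of the condition's chromatin background and evaluates the model.
    """
    effective = apply_condition(condition, params.affinities, residual=residual)
    result = evaluate(effective, params.interactions, params.h(condition.chromatin))
    return result.pBinding
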