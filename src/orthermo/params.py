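"""Model parameters: binding affinities, interaction factors, epigenetic factors.

The model describes occupancy of five DNA sites (two Homeobox sites, a shared
Pou site, an Ebox and the TATA box) by three transcription factors — Acj6 (A),
Pdm3 (B), Fer1 (C) — and RNA polymerase (R).  Each ligand j carries a
dimensionless affinity ratio ``q_j = [j]/K_j`` (bound/unbound odds at its
site); co-bound pairs carry interaction factors ``w_jn`` (cooperative > 1,
competitive < 1); chromatin state multiplies defined Fer1-bound configuration
classes by epigenetic factors ``h_m``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Mapping, Tuple

__all__ = [
    "ChromatinState",
    "BindingAffinities",
    "InteractionFactors",
    "EpigeneticFactors",
    "ParameterSet",
    "ConcentrationModel",
    "q_from_concentration",
    "Q_NAMES",
    "W_NAMES",
    "H_NAMES",
    "QW_RANGES",
    "QA_QB_PRODUCT_RANGE",
    "NOMINAL_H",
    "RESIDUAL_RANGE",
    "DEFAULT_RESIDUAL",
]


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its positivity/range contract."""


class ChromatinState(enum.Enum):
    """Chromatin background of an experiment.

    C: normal ("closed") chromatin; H: heterozygous su(var)3-9 mutant
    ("open"); N: homozygous su(var)3-9 mutant ("more open").
    """

    C = "C"
    H = "H"
    N = "N"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Canonical orderings used by the vectorised engine and all CSV output.
Q_NAMES: Tuple[str, ...] = ("qR", "qA1", "qA2", "qB1", "qB2", "qC")
W_NAMES: Tuple[str, ...] = ("wA1A2", "wB1B2", "wA1B2", "wB1A2", "wCR")
H_NAMES: Tuple[str, ...] = ("h1", "h2", "h3", "hA", "hB")

# Sampling ranges for the uniform random search.  qA1·qA2 and qB1·qB2 are
# additionally constrained to the single-parameter range.
QW_RANGES: Dict[str, Tuple[float, float]] = {
    "qR": (0.002, 0.03),
    "qA1": (0.1, 2500.0),
    "qA2": (0.1, 2500.0),
    "qB1": (0.1, 2500.0),
    "qB2": (0.1, 2500.0),
    "qC": (0.1, 2500.0),
    "wA1A2": (10.0, 100.0),
    "wB1B2": (10.0, 100.0),
    "wA1B2": (0.0002, 0.001),
    "wB1A2": (0.0002, 0.001),
    "wCR": (30.0, 100.0),
}
QA_QB_PRODUCT_RANGE: Tuple[float, float] = (0.1, 2500.0)

# Nominal epigenetic factors per chromatin state.  Per-sample values are
# drawn from Normal(mean, mean/10), truncated to positive values.
NOMINAL_H: Dict[ChromatinState, Dict[str, float]] = {
    ChromatinState.C: {"h1": 1.0, "h2": 0.00007, "h3": 0.0002, "hA": 30.0, "hB": 5.0},
    ChromatinState.H: {"h1": 0.9, "h2": 0.00008, "h3": 0.00035, "hA": 100.0, "hB": 0.1},
    ChromatinState.N: {"h1": 0.8, "h2": 0.0001, "h3": 0.0005, "hA": 150.0, "hB": 0.05},
}

# A mutated binding motif retains a residual affinity orders of magnitude
# below the functional range; default is the log-midpoint of the range.
RESIDUAL_RANGE: Tuple[float, float] = (1e-6, 1e-5)
DEFAULT_RESIDUAL: float = 10 ** -5.5


def _check_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class BindingAffinities:
    """Bound/unbound odds ratios q_j for the six ligand-site pairs.

    qA = qA1*qA2 and qB = qB1*qB2 are derived quantities describing double
    binding of the two-domain Pou-Homeobox proteins; they never enter a
    statistical weight directly but are range-constrained during sampling.
    """

    qR: float
    qA1: float
    qA2: float
    qB1: float
    qB2: float
    qC: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name))

    @property
    def qA(self) -> float:
        return self.qA1 * self.qA2

    @property
    def qB(self) -> float:
        return self.qB1 * self.qB2

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in Q_NAMES}

    def replace(self, **kwargs: float) -> "BindingAffinities":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InteractionFactors:
    """TF–TF and TF–RNAp interaction factors w_jn.

    wA1A2, wB1B2: cooperativity of double binding of Acj6 resp. Pdm3;
    wA1B2, wB1A2: competition between a Homeobox-bound TF and the other TF
    on the Pou site; wCR: cooperativity between Ebox-bound Fer1 and RNAp.
    """

    wA1A2: float
    wB1B2: float
    wA1B2: float
    wB1A2: float
    wCR: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name))

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in W_NAMES}

    def replace(self, **kwargs: float) -> "InteractionFactors":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EpigeneticFactors:
    """Chromatin-state-dependent multipliers h_m on Fer1-bound state classes.

    h1: Fer1 bound, no Acj6/Pdm3 anywhere on the cluster; h2: Fer1 bound,
    Pou empty, at least one Homeobox bound; h3: Fer1 bound and Pou occupied;
    hA/hB: remodulation of the wA1A2/wB1B2 cooperativities when Fer1 is bound.
    """

    h1: float
    h2: float
    h3: float
    hA: float
    hB: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name))

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in H_NAMES}

    @classmethod
    def nominal(cls, chromatin: ChromatinState) -> "EpigeneticFactors":
        """The shipped nominal values for a chromatin state."""
        return cls(**NOMINAL_H[chromatin])


@dataclass(frozen=True)
class ParameterSet:
    """A full model parameterisation: 13 q/w quantities plus 3×5 h values.

    Counting qA and qB (derived) the q/w block registers 13 quantities; the
    free parameters number 18 when each h_m is counted once (q_R, q_A1, q_A2,
    q_B1, q_B2, q_C, five w, five h — with q_A, q_B determined by products).
    """

    affinities: BindingAffinities
    interactions: InteractionFactors
    epigenetics: Mapping[ChromatinState, EpigeneticFactors] = field(
        default_factory=lambda: {s: EpigeneticFactors.nominal(s) for s in ChromatinState}
    )

    N_QW_QUANTITIES = 13  # 8 binding entries (incl. derived qA, qB) + 5 interactions
    N_FREE_PARAMETERS = 18  # 6 q + 5 w + 5 h (each h counted once), qA/qB derived

    def h(self, chromatin: ChromatinState) -> EpigeneticFactors:
        return self.epigenetics[chromatin]

    def as_flat_dict(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        out.update(self.affinities.as_dict())
        out.update(self.interactions.as_dict())
        for state in ChromatinState:
            for name, value in self.epigenetics[state].as_dict().items():
                out[f"{name}_{state.value}"] = value
        return out

    @classmethod
    def with_nominal_h(
        cls, affinities: BindingAffinities, interactions: InteractionFactors
    ) -> "ParameterSet":
        return cls(affinities=affinities, interactions=interactions)


@dataclass(frozen=True)
class ConcentrationModel:
    """A ligand concentration paired with its equilibrium dissociation constant."""

    concentration: float
    K: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidParameterError("concentration must be nonnegative")
        if not (self.K > 0):
            raise InvalidParameterError("dissociation constant K must be positive")


def q_from_concentration(conc: ConcentrationModel) -> float:
    """Affinity ratio q = [X]/K from a concentration model.

    The site occupancy probability follows as q/(1+q); K is the ligand
    concentration giving half occupancy.
    """
    return conc.concentration / conc.K


def occupancy_probability(q: float) -> float:
    """Fractional site occupancy q/(1+q) for a single isolated site."""
    if q < 0:
        raise InvalidParameterError("q must be nonnegative")
    return q / (1.0 + q)
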