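"""Thermodynamic core: state enumeration, factor rules, weights, P_binding."""

import math
from pathlib import Path

import numpy as np
import pytest

from orthermo import (
    BindingAffinities,
    ChromatinState,
    ConcentrationModel,
    Configuration,
    EpigeneticFactors,
    InteractionFactors,
    active_factors,
    enumerate_states,
    evaluate,
    q_from_concentration,
    state_table_frame,
    state_weight,
)
from orthermo.params import occupancy_probability
from orthermo.states import EMPTY, rnap_bound_indices

from conftest import random_parameters


def brute_force_weights(affinities, interactions, epigenetics):
    """Independent oracle: literal transcription of the factor rules.

    Loops over all (hoxA, hoxB, pou, ebox, tata) tuples and multiplies the
    applicable factors directly, without touching the package's exponent
    matrices or canonical ordering machinery.
    """
    weights = {}
    for hoxA in (EMPTY, "A1"):
        for hoxB in (EMPTY, "B1"):
            for pou in (EMPTY, "A2", "B2"):
                for ebox in (EMPTY, "C"):
                    for tata in (EMPTY, "R"):
                        w = 1.0
                        a1, b1 = hoxA == "A1", hoxB == "B1"
                        a2, b2 = pou == "A2", pou == "B2"
                        c, r = ebox == "C", tata == "R"
                        if a1:
                            w *= affinities.qA1
                        if b1:
                            w *= affinities.qB1
                        if a2:
                            w *= affinities.qA2
                        if b2:
                            w *= affinities.qB2
                        if c:
                            w *= affinities.qC
                        if r:
                            w *= affinities.qR
                        if a1 and a2:
                            w *= interactions.wA1A2
                        if b1 and b2:
                            w *= interactions.wB1B2
                        if a1 and b2:
                            w *= interactions.wA1B2
                        if b1 and a2:
                            w *= interactions.wB1A2
                        # Fer1-RNAp cooperativity requires Fer1 to be held in
                        # place by at least one other TF on the cluster.
                        if c and r and (a1 or b1 or a2 or b2):
                            w *= interactions.wCR
                        if c:
                            anyone = a1 or b1 or a2 or b2
                            if not anyone:
                                w *= epigenetics.h1
                            if not (a2 or b2) and (a1 or b1):
                                w *= epigenetics.h2
                            if a2 or b2:
                                w *= epigenetics.h3
                            if a1 and a2:
                                w *= epigenetics.hA
                            if b1 and b2:
                                w *= epigenetics.hB
                        weights[(hoxA, hoxB, pou, ebox, tata)] = w
    return weights


class TestEnumeration:
    def test_counts(self):
        states = enumerate_states()
        assert len(states) == 48
        assert len({c.index for c in states}) == 48
        assert sum(c.rnap_bound for c in states) == 24
        assert sum(c.pou == "A2" for c in states) == 16

    def test_rnap_block_is_upper_half(self):
        assert rnap_bound_indices() == list(range(25, 49))

    @pytest.mark.parametrize(
        "index, occupancy",
        [
            (6, "A1+B1"),
            (9, "B1+B2"),
            (13, "B1+B2+C"),
            (14, "A1+A2+C"),
            (21, "C"),
            (37, "B1+B2+C+R"),
            (38, "A1+A2+C+R"),
            (41, "B2+C+R"),
            (42, "A2+C+R"),
            (45, "C+R"),
            (48, "A1+B1+C+R"),
        ],
    )
    def test_canonical_anchors(self, index, occupancy):
        """Landmark states named in the analysis keep their canonical indices."""
        states = enumerate_states()
        assert states[index - 1].occupancy_description == occupancy

    def test_mirror_pairs_share_cluster_occupancy(self):
        states = enumerate_states()
        for k in range(24):
            low, high = states[k], states[k + 24]
            assert (low.hoxA, low.hoxB, low.pou, low.ebox) == (
                high.hoxA,
                high.hoxB,
                high.pou,
                high.ebox,
            )
            assert low.tata == EMPTY and high.tata == "R"

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            Configuration(index=1, hoxA="B1", hoxB=EMPTY, pou=EMPTY, ebox=EMPTY, tata=EMPTY)

    def test_shipped_state_table_matches_enumeration(self):
        import pandas as pd

        shipped = Path(__file__).resolve().parents[1] / "src/orthermo/data/state_table.csv"
        assert state_table_frame().equals(pd.read_csv(shipped))


class TestActiveFactors:
    def test_rnap_alone(self):
        config = Configuration(25, EMPTY, EMPTY, EMPTY, EMPTY, "R")
        assert active_factors(config) == {"qR"}

    def test_bare_fer1_carries_h1_but_no_rnap_cooperativity(self):
        config = Configuration(21, EMPTY, EMPTY, EMPTY, "C", EMPTY)
        assert active_factors(config) == {"qC", "h1"}
        with_rnap = Configuration(45, EMPTY, EMPTY, EMPTY, "C", "R")
        # Fer1 with no other TF anywhere cannot co-recruit the polymerase.
        assert active_factors(with_rnap) == {"qC", "qR", "h1"}

    def test_acj6_double_bound_with_fer1_and_rnap(self):
        config = Configuration(38, "A1", EMPTY, "A2", "C", "R")
        assert active_factors(config) == {
            "qA1",
            "qA2",
            "qC",
            "qR",
            "wA1A2",
            "wCR",
            "hA",
            "h3",
        }

    def test_mirror_symmetry_of_factor_sets(self):
        """State k+24 adds qR, plus wCR exactly when Fer1 is stabilised."""
        states = enumerate_states()
        for k in range(24):
            low = active_factors(states[k])
            high = active_factors(states[k + 24])
            c = states[k].ebox == "C"
            stabilised = c and (
                states[k].hoxA == "A1" or states[k].hoxB == "B1" or states[k].pou != EMPTY
            )
            expected = set(low) | {"qR"} | ({"wCR"} if stabilised else set())
            assert high == expected


class TestWeightsAndEvaluation:
    def test_empty_configuration_weight_is_one(self):
        rng = np.random.default_rng(0)
        q, w, h = random_parameters(rng)
        empty = Configuration(1, EMPTY, EMPTY, EMPTY, EMPTY, EMPTY)
        assert state_weight(empty, q, w, h) == pytest.approx(1.0)

    def test_single_factor_weight(self):
        q = BindingAffinities(qR=0.03, qA1=1, qA2=1, qB1=1, qB2=1, qC=1)
        w = InteractionFactors(wA1A2=10, wB1B2=10, wA1B2=0.001, wB1A2=0.001, wCR=50)
        h = EpigeneticFactors.nominal(ChromatinState.C)
        config = Configuration(25, EMPTY, EMPTY, EMPTY, EMPTY, "R")
        assert state_weight(config, q, w, h) == pytest.approx(0.03)

    def test_bare_fer1_rnap_weight_has_no_cooperativity(self):
        # qC·qR·h1 only: the wCR term does not act when Fer1 binds alone.
        q = BindingAffinities(qR=0.03, qA1=1, qA2=1, qB1=1, qB2=1, qC=10)
        w = InteractionFactors(wA1A2=10, wB1B2=10, wA1B2=0.001, wB1A2=0.001, wCR=50)
        h = EpigeneticFactors(h1=1.0, h2=1e-4, h3=2e-4, hA=30, hB=5)
        config = Configuration(45, EMPTY, EMPTY, EMPTY, "C", "R")
        assert state_weight(config, q, w, h) == pytest.approx(10 * 0.03 * 1.0, rel=1e-12)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            BindingAffinities(qR=0.0, qA1=1, qA2=1, qB1=1, qB2=1, qC=1)
        with pytest.raises(ValueError):
            EpigeneticFactors(h1=-1, h2=1, h3=1, hA=1, hB=1)

    def test_brute_force_oracle_equivalence(self):
        """All 48 weights match a literal transcription of the factor rules."""
        rng = np.random.default_rng(42)
        states = enumerate_states()
        for _ in range(200):
            q, w, h = random_parameters(rng)
            oracle = brute_force_weights(q, w, h)
            for config in states:
                expected = oracle[(config.hoxA, config.hoxB, config.pou, config.ebox, config.tata)]
                got = state_weight(config, q, w, h)
                assert got == pytest.approx(expected, rel=1e-10)

    def test_probabilities_normalised(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            q, w, h = random_parameters(rng)
            result = evaluate(q, w, h)
            assert result.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
            assert 0.0 < result.pBinding < 1.0

    def test_pbinding_equals_rnap_block_mass(self):
        rng = np.random.default_rng(2)
        q, w, h = random_parameters(rng)
        result = evaluate(q, w, h)
        assert result.pBinding == pytest.approx(result.probabilities[24:].sum(), rel=1e-12)
        assert result.Ztot == pytest.approx(result.weights.sum(), rel=1e-12)

    def test_decoupling_closed_form(self):
        """wCR = 1 makes the polymerase independent: P_binding = qR/(1+qR)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            q, w, h = random_parameters(rng)
            w1 = w.replace(wCR=1.0)
            result = evaluate(q, w1, h)
            assert result.pBinding == pytest.approx(q.qR / (1 + q.qR), rel=1e-12)

    def test_decoupling_example_value(self):
        q = BindingAffinities(qR=0.03, qA1=5, qA2=7, qB1=3, qB2=11, qC=13)
        w = InteractionFactors(wA1A2=50, wB1B2=20, wA1B2=0.0005, wB1A2=0.0003, wCR=1.0)
        h = EpigeneticFactors.nominal(ChromatinState.C)
        assert evaluate(q, w, h).pBinding == pytest.approx(0.03 / 1.03, rel=1e-9)

    def test_monotonicity_in_qR_wCR_and_qC(self):
        rng = np.random.default_rng(4)
        q, w, h = random_parameters(rng)
        base = evaluate(q, w, h).pBinding
        assert evaluate(q.replace(qR=q.qR * 1.5), w, h).pBinding > base
        assert evaluate(q, w.replace(wCR=w.wCR * 1.5), h).pBinding > base
        if w.wCR > 1:
            assert evaluate(q.replace(qC=q.qC * 1.5), w, h).pBinding > base


class TestHillRelations:
    @pytest.mark.parametrize(
        "conc, K, q, occ",
        [(2.0, 2.0, 1.0, 0.5), (0.0, 5.0, 0.0, 0.0), (6.0, 2.0, 3.0, 0.75)],
    )
    def test_q_from_concentration(self, conc, K, q, occ):
        model = ConcentrationModel(concentration=conc, K=K)
        ratio = q_from_concentration(model)
        assert ratio == pytest.approx(q)
        assert occupancy_probability(ratio) == pytest.approx(occ)

    def test_invalid_dissociation_constant(self):
        with pytest.raises(ValueError):
            ConcentrationModel(concentration=1.0, K=0.0)
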