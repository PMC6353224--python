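"""Cost function, samplers, monotonicity and the staged random search."""

import numpy as np
import pytest

from orthermo import (
    ChromatinState,
    EpigeneticFactors,
    ExpressionInterval,
    FitConfig,
    check_h_monotonicity,
    default_truth_table,
    perturb_h,
    phi,
    run_fit,
    sample_qw,
    set_distance,
    tune_h,
)
from orthermo.fitting import sample_qw_arrays
from orthermo.params import (
    H_NAMES,
    NOMINAL_H,
    ParameterSet,
    QA_QB_PRODUCT_RANGE,
    QW_RANGES,
    Q_NAMES,
    W_NAMES,
)
from orthermo.truth_table import TruthTable, all_conditions

from conftest import random_parameters


def all_unit_table():
    """Truth table with the maximal interval everywhere (never constrains)."""
    from orthermo.truth_table import ExpressionInterval as EI

    return TruthTable(
        {(c.row, c.chromatin): EI(0.0, 1.0) for c in all_conditions()}
    )


class TestSetDistance:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.5, 0.1), (0.7, 0.0), (1.2, 0.2)],
    )
    def test_examples(self, x, expected):
        assert set_distance(x, ExpressionInterval(0.6, 1.0)) == pytest.approx(expected)

    def test_interval_distance_is_pointwise_minimum(self):
        interval = ExpressionInterval(0.3, 0.7)
        xs = np.linspace(0, 1, 101)
        for x in xs:
            direct = min(abs(x - y) for y in np.linspace(0.3, 0.7, 401))
            assert interval.distance(float(x)) == pytest.approx(direct, abs=2e-3)


class TestPhi:
    def test_unconstrained_table_scores_zero(self):
        rng = np.random.default_rng(0)
        q, w, h = random_parameters(rng)
        params = ParameterSet.with_nominal_h(q, w)
        assert phi(params, all_unit_table()) == 0.0

    def test_single_cell_violation_equals_its_distance(self, table):
        rng = np.random.default_rng(1)
        q, w, _ = random_parameters(rng)
        params = ParameterSet.with_nominal_h(q, w)
        from orthermo import condition_pbinding

        total = 0.0
        for condition in all_conditions():
            p = condition_pbinding(params, condition)
            total += table.interval(condition).distance(p)
        assert phi(params, table) == pytest.approx(total, rel=1e-12)

    def test_column_restrictions_sum_to_total(self, table):
        rng = np.random.default_rng(2)
        q, w, _ = random_parameters(rng)
        params = ParameterSet.with_nominal_h(q, w)
        parts = [phi(params, table, columns=[s]) for s in ChromatinState]
        assert sum(parts) == pytest.approx(phi(params, table), rel=1e-12)


class TestSamplers:
    def test_qw_draws_respect_ranges_and_product_constraint(self):
        config = FitConfig(seed=0)
        draws = sample_qw(config, 500)
        lo_p, hi_p = QA_QB_PRODUCT_RANGE
        for q, w in draws:
            for name in Q_NAMES:
                lo, hi = QW_RANGES[name]
                assert lo <= getattr(q, name) <= hi
            for name in W_NAMES:
                lo, hi = QW_RANGES[name]
                assert lo <= getattr(w, name) <= hi
            assert lo_p < q.qA < hi_p
            assert lo_p < q.qB < hi_p

    def test_qw_sampling_deterministic_under_seed(self):
        config = FitConfig(seed=123)
        rng1 = np.random.default_rng(123)
        rng2 = np.random.default_rng(123)
        a = sample_qw_arrays(config, 1000, rng1)
        b = sample_qw_arrays(config, 1000, rng2)
        np.testing.assert_array_equal(a, b)

    def test_perturb_h_moments(self):
        nominal = EpigeneticFactors.nominal(ChromatinState.C)
        draws = perturb_h(nominal, 10_000, seed=5)
        means = np.array([getattr(nominal, n) for n in H_NAMES])
        assert np.allclose(draws.mean(axis=0), means, rtol=0.02)
        assert np.allclose(draws.std(axis=0), means / 10, rtol=0.1)
        assert (draws > 0).all()

    def test_perturb_h_zero_sd_returns_nominal(self):
        nominal = EpigeneticFactors.nominal(ChromatinState.H)
        draws = perturb_h(nominal, 7, seed=0, rel_sd=0.0)
        expected = np.array([getattr(nominal, n) for n in H_NAMES])
        assert np.allclose(draws, expected)


class TestMonotonicity:
    def test_nominal_values_follow_the_trend(self):
        hC, hH, hN = (EpigeneticFactors.nominal(s) for s in ChromatinState)
        assert check_h_monotonicity(hC, hH, hN)

    def test_swapped_pair_fails(self):
        hC, hH, hN = (EpigeneticFactors.nominal(s) for s in ChromatinState)
        # hA decreased H -> N: violates the increasing requirement
        bad_n = EpigeneticFactors(h1=hN.h1, h2=hN.h2, h3=hN.h3, hA=hH.hA * 0.5, hB=hN.hB)
        assert not check_h_monotonicity(hC, hH, bad_n)

    def test_ties_fail(self):
        hC, hH, hN = (EpigeneticFactors.nominal(s) for s in ChromatinState)
        tied = EpigeneticFactors(h1=hH.h1, h2=hN.h2, h3=hN.h3, hA=hN.hA, hB=hN.hB)
        assert not check_h_monotonicity(hC, hH, tied)


class TestRunFit:
    def test_huge_tau_retains_everything(self):
        config = FitConfig(seed=1, tau=100.0, total_samples=2000, batch_size=2000)
        ensemble = run_fit(config, default_truth_table())
        assert ensemble.n_retained == ensemble.n_sampled == 2000

    def test_bookkeeping_conserves_counts(self, small_ensemble):
        assert small_ensemble.n_sampled == (
            small_ensemble.n_filtered_out + small_ensemble.n_retained
        )
        assert small_ensemble.n_retained >= small_ensemble.n_feasible_ch
        assert small_ensemble.n_feasible_ch >= small_ensemble.n_feasible_all

    def test_unconstrained_table_makes_every_sample_feasible(self):
        config = FitConfig(seed=2, total_samples=3000, batch_size=3000)
        ensemble = run_fit(config, all_unit_table())
        assert ensemble.n_retained == 3000
        assert ensemble.n_feasible_all == 3000
        assert ensemble.fraction_feasible_all == pytest.approx(1.0)

    def test_seeded_runs_bit_reproducible(self):
        config = FitConfig(seed=11, tau=0.8, total_samples=20_000, batch_size=10_000)
        table = default_truth_table()
        a = run_fit(config, table)
        b = run_fit(config, table)
        assert a.n_retained == b.n_retained
        assert a.samples.equals(b.samples)

    def test_empty_result_is_structured(self):
        # A tiny budget cannot pass the filter; the result reports diagnostics.
        config = FitConfig(seed=3, total_samples=2000, batch_size=2000)
        ensemble = run_fit(config, default_truth_table())
        assert ensemble.n_retained == 0
        assert ensemble.samples.empty
        assert np.isnan(ensemble.fraction_phiN_pass)
        assert ensemble.diagnostics["retained_fraction"] == 0.0

    def test_retained_samples_satisfy_filter(self, small_ensemble):
        tau = small_ensemble.config.tau
        assert (small_ensemble.samples["phi_C"] < tau).all()
        assert (small_ensemble.samples["phi_H"] < tau).all()

    def test_weights_normalised(self, small_ensemble):
        assert small_ensemble.weights.sum() == pytest.approx(1.0)
        assert 0 < small_ensemble.effective_sample_size <= small_ensemble.n_retained

    def test_n_stage_h_draws_respect_the_monotone_trend(self, small_ensemble):
        hH = small_ensemble.h_draws["H"]
        hN = small_ensemble.h_draws["N"]
        inc = [H_NAMES.index(n) for n in ("h2", "h3", "hA")]
        dec = [H_NAMES.index(n) for n in ("h1", "hB")]
        assert (hN[..., inc] > hH[..., inc]).all()
        assert (hN[..., dec] < hH[..., dec]).all()


class TestTuneH:
    def test_already_satisfied_target_returns_input(self):
        config = FitConfig(seed=4, total_samples=5000)
        tuned, diagnostics = tune_h(
            config, all_unit_table(), stage=ChromatinState.H, n_eval_samples=2000, n_iters=5
        )
        assert diagnostics["initial_score"] == 1.0
        assert diagnostics["improved"] == 0.0
        assert tuned.as_dict() == dict(NOMINAL_H[ChromatinState.H])

    def test_monotone_violating_candidates_are_rejected_at_stage_n(self):
        config = FitConfig(seed=5)
        tuned, diagnostics = tune_h(
            config,
            default_truth_table(),
            stage=ChromatinState.N,
            n_eval_samples=2000,
            n_iters=30,
            step_sd=1.5,  # large steps: most candidates break the trend
        )
        assert diagnostics["rejected_monotone"] > 0
        hC = EpigeneticFactors.nominal(ChromatinState.C)
        hH = EpigeneticFactors.nominal(ChromatinState.H)
        assert check_h_monotonicity(hC, hH, tuned)

    def test_stage_c_is_rejected(self):
        with pytest.raises(ValueError):
            tune_h(FitConfig(seed=0), default_truth_table(), stage=ChromatinState.C)
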