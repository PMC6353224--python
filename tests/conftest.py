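import numpy as np
import pytest

from orthermo import (
    BindingAffinities,
    ChromatinState,
    EpigeneticFactors,
    FitConfig,
    InteractionFactors,
    default_truth_table,
    run_fit,
)
from orthermo.params import H_NAMES, QW_RANGES, Q_NAMES, W_NAMES


def random_parameters(rng):
    """One (affinities, interactions, epigenetics) triple drawn inside the
    sampling ranges, with Table-scale epigenetic values."""
    q = {}
    for name in Q_NAMES:
        lo, hi = QW_RANGES[name]
        q[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    w = {}
    for name in W_NAMES:
        lo, hi = QW_RANGES[name]
        w[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    state = rng.choice(list(ChromatinState))
    nominal = EpigeneticFactors.nominal(state)
    h = {
        name: float(getattr(nominal, name) * np.exp(rng.normal(0, 0.2)))
        for name in H_NAMES
    }
    return BindingAffinities(**q), InteractionFactors(**w), EpigeneticFactors(**h)


@pytest.fixture(scope="session")
def table():
    return default_truth_table()


@pytest.fixture(scope="session")
def small_ensemble(table):
    """A small importance-sampled fit of the experimental table.

    Sized for roughly a minute of runtime; shared across reporting tests.
    """
    config = FitConfig(
        seed=7,
        batch_size=250_000,
        total_samples=2_000_000,
        target_retained=120,
        sampling="importance",
        adapt_samples=100_000,
        adapt_iters=4,
        adapt_elite=300,
    )
    ensemble = run_fit(config, table)
    assert ensemble.n_retained > 0, "fit fixture produced no retained samples"
    return ensemble
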