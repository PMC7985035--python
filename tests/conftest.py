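import numpy as np
import pytest

from coxfuse import SimulationSpec, SurvivalDataset, simulate_survival


def random_survival(seed, n=50, censoring=0.3):
    """Small random censored dataset for oracle-equality checks."""
    rng = np.random.default_rng(seed)
    T = rng.exponential(10.0, n)
    d = (rng.random(n) > censoring).astype(int)
    if d.sum() == 0:
        d[rng.integers(n)] = 1
    eta = rng.standard_normal(n)
    return eta, T, d


@pytest.fixture(scope="session")
def strong_signal():
    """Planted-signal cohort shared by the slower model tests."""
    ds, eta = simulate_survival(SimulationSpec(n=300, p=30, n_informative=3,
                                               seed=123))
    return ds, eta


@pytest.fixture
def tiny_dataset():
    return SurvivalDataset(
        ["a", "b", "c", "d"],
        np.arange(8.0).reshape(4, 2),
        [5.0, 3.0, 8.0, 1.0],
        [1, 1, 0, 1],
    )
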