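import numpy as np
import pytest

from vibrohist.synthetic_data import ObserverParams, simulate_dataset

# Shared synthetic datasets. Sizes are chosen so history effects are
# estimable with comfortable margin while keeping the suite fast.


@pytest.fixture(scope="session")
def continuous_dataset():
    """60 sessions x 300 trials from a continuous criterion-updating observer
    (tau = 30 s), the study-like default generator."""
    return simulate_dataset(
        n_sessions=60,
        trials_per_session=300,
        params=ObserverParams(model_type="continuous", tau=30.0, sigma=1.2,
                              gamma=0.05, lam=0.05),
        seed=123,
    )


@pytest.fixture(scope="session")
def discrete_dataset():
    """60 sessions x 300 trials from a discrete observer with tau = 4 trials."""
    return simulate_dataset(
        n_sessions=60,
        trials_per_session=300,
        params=ObserverParams(model_type="discrete", tau=4.0, sigma=1.2,
                              gamma=0.05, lam=0.05),
        seed=456,
    )


@pytest.fixture(scope="session")
def memoryless_dataset():
    """20 sessions x 300 trials from a static (no-history) observer."""
    return simulate_dataset(
        n_sessions=20,
        trials_per_session=300,
        params=ObserverParams(model_type="no-history", sigma=1.2,
                              gamma=0.05, lam=0.05),
        seed=789,
    )


@pytest.fixture(scope="session")
def static_50k_dataset():
    """~50k static-observer trials with asymmetric lapses, for parameter
    recovery of the psychometric fit (true mu0=0.5, sigma=1.2, gamma=0.05,
    lambda=0.08)."""
    return simulate_dataset(
        n_sessions=167,
        trials_per_session=300,
        params=ObserverParams(model_type="no-history", mu0=0.5, sigma=1.2,
                              gamma=0.05, lam=0.08),
        seed=2024,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
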