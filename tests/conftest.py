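import numpy as np
import pytest

from ricerisk import SimulationConfig, simulate_dataset, build_indicator_series


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured synthetic dataset shared across tests."""
    cfg = SimulationConfig(
        n_provinces=6, n_weeks=60, samples_per_province_week=20, seed=42
    )
    samples, consumption, regimes = simulate_dataset(cfg)
    return cfg, samples, consumption, regimes


@pytest.fixture(scope="session")
def small_series(small_dataset):
    _, samples, consumption, _ = small_dataset
    return build_indicator_series(samples, consumption)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
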