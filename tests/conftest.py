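import numpy as np
import pandas as pd
import pytest

from nichetrack.synthetic import SimulationConfig, generate_environment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact simulation: 300 km domain, one year, hourly fixes."""
    return SimulationConfig(
        n_individuals=2, years=1, fix_interval_min=60,
        extent_km=300, cell_km=10, seed=2024,
    )


@pytest.fixture(scope="session")
def small_env(small_config):
    return generate_environment(small_config)


@pytest.fixture(scope="session")
def zero_noise_env():
    cfg = SimulationConfig(
        years=2, extent_km=200, cell_km=10,
        noise_scales={"temperature": 0.0, "precipitation": 0.0, "ndvi": 0.0},
        seed=7,
    )
    return generate_environment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track_df(timestamps, x, y):
    return pd.DataFrame(
        {"timestamp": pd.to_datetime(timestamps), "x_km": x, "y_km": y}
    )
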