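import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import elsquant as e

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """A small field that still fits two default-size aggregates."""
    return e.SimulationConfig(
        field_width_px=512, field_height_px=512, n_aggregates=2,
        nuclei_per_aggregate=(60, 120),
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    return e.simulate_field(small_config, seed=11)


@pytest.fixture(scope="session")
def otsu_specs():
    return (
        e.ThresholdSpec("CD3", method="otsu"),
        e.ThresholdSpec("B220", method="otsu"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
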