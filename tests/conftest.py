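import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def step():
    """Striped calibration substrate: 4/40 kPa, 100/200 µm stripes, 40 µm ramps."""
    from durokit.substrates import step_pattern

    return step_pattern()


@pytest.fixture
def shallow():
    """Shallow gradient substrate: 4→40 kPa over 1,000 µm (36 Pa/µm)."""
    from durokit.substrates import gradient_pattern

    return gradient_pattern()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
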