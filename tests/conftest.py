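import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from admitsense import reference_calibration

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quadratic_calibration():
    """Shipped quadratic response surfaces of the prototype device."""
    return reference_calibration("quadratic")


@pytest.fixture(scope="session")
def linear_calibration():
    """Shipped linear response surfaces (quadrature rows drive the init)."""
    return reference_calibration("linear")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
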