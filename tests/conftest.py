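import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def vm_degrees(rng, mu_deg: float, kappa: float, n: int) -> np.ndarray:
    """Reference von Mises sampler used as an independent data source."""
    return np.degrees(rng.vonmises(np.radians(mu_deg), kappa, n)) % 360.0


@pytest.fixture
def unimodal_sample(rng):
    return vm_degrees(rng, 120.0, 2.0, 500)
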