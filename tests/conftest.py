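import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aihtct as a

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bank():
    return a.build_filter_bank()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_geometry():
    """[0, 90) limited-angle geometry matched to a 32x32 image."""
    return a.limited_angle_geometry((0, 90), 30, a.default_detector_count(32))


@pytest.fixture(scope="session")
def square32():
    img = np.zeros((32, 32))
    img[8:24, 8:24] = 0.5
    return img
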