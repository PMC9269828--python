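import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colowave import ArrayGeometry, build_measurement_plan
from colowave.focuser import ImageGrid

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def plan(geometry):
    return build_measurement_plan(geometry)


@pytest.fixture(scope="session")
def grid():
    return ImageGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
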