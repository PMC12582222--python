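import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hvctrack.expansion_model import PointCloud

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_cloud(rng):
    """100 uniform points in the default 500 µm cube centered at 0."""
    xyz = rng.uniform(-250.0, 250.0, size=(100, 3))
    return PointCloud(ids=tuple(range(100)), xyz=xyz, side=500.0)


@pytest.fixture
def tiny_cloud():
    return PointCloud(
        ids=("a", "b", "c"),
        xyz=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        side=10.0,
    )
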