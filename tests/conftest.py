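import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pose():
    from flyfluor import TrajectoryRecord

    return TrajectoryRecord(frame=0, fly_id=0, x=10.0, y=10.0, theta=0.0, a=5.0, b=2.0)


def random_pose(rng, frame=0, fly_id=0, span=100.0):
    """A random valid pose, possibly near or beyond image edges."""
    from flyfluor import TrajectoryRecord

    b = rng.uniform(1.0, 6.0)
    a = b + rng.uniform(0.0, 8.0)
    return TrajectoryRecord(
        frame=frame,
        fly_id=fly_id,
        x=rng.uniform(-10.0, span + 10.0),
        y=rng.uniform(-10.0, span + 10.0),
        theta=rng.uniform(-np.pi, np.pi),
        a=a,
        b=b,
    )
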