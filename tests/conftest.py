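import numpy as np
import pytest

from isoqa.geometry import BeamGeometry, Pose6D
from isoqa.phantom import default_phantom


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def geom():
    return BeamGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_qa_pose(rng, t_max=2.0, r_max=1.0) -> Pose6D:
    """A random pose within the QA regime (|t| <= t_max mm, |r| <= r_max deg)."""
    t = rng.uniform(-t_max, t_max, size=3)
    r = rng.uniform(-r_max, r_max, size=3)
    return Pose6D(vrt_mm=t[0], lng_mm=t[1], lat_mm=t[2],
                  pitch_deg=r[0], roll_deg=r[1], rtn_deg=r[2])
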