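import numpy as np
import pytest

from rungwalk.geometry import CourseGeometry, scaled_fixture_geometry
from rungwalk.synth.crossing import CrossingStyle


@pytest.fixture(scope="session")
def geometry() -> CourseGeometry:
    """Reduced-resolution course geometry used by most fixtures."""
    return scaled_fixture_geometry()


@pytest.fixture(scope="session")
def quiet_style() -> CrossingStyle:
    """Deterministic, low-variability crossing style for exact checks."""
    return CrossingStyle(speed_jitter_sd=0.0,
                         stable_offset_sd=(0.0, 0.0),
                         unstable_offset_sd=(0.0, 0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
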