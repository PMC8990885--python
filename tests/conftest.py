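import numpy as np
import pytest

from carbonmc import WATER, make_water_phantom
from carbonmc.fragmentation import default_tables


@pytest.fixture
def rng():
    return np.random.default_rng(20220325)


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture
def coarse_phantom():
    """10 x 10 x 40 cm water box, 5 mm transverse / 0.5 mm depth voxels."""
    return make_water_phantom((10, 10, 40), (5.0, 5.0, 0.5))


@pytest.fixture
def water():
    return WATER
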