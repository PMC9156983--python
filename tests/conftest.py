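import numpy as np
import pytest

from osteopore import CalibratedVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_volume():
    """16³ volume at a uniform 1000 mg HA/ccm, 2 µm voxels."""
    return CalibratedVolume(np.full((16, 16, 16), 1000.0), voxel_size=2.0)
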