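import numpy as np
import pytest

from habitatrad.imaging import ImageVolume, RegionMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cube_volume(rng):
    """24^3 noise volume with a centred 12^3 cubic region mask."""
    vol = ImageVolume(rng.normal(size=(24, 24, 24)))
    m = np.zeros((24, 24, 24), dtype=bool)
    m[6:18, 6:18, 6:18] = True
    return vol, RegionMask(m)


@pytest.fixture
def ball_mask():
    """Digital ball of radius 5 voxels centred in a 24^3 grid."""
    idx = np.indices((24, 24, 24)).astype(float)
    r2 = ((idx - 11.5) ** 2).sum(axis=0)
    return RegionMask(r2 <= 5.0**2 + 1e-9)
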