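import numpy as np
import pytest

from suturemap.datatypes import BoneMask, ProjectedImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask(rng):
    """A sparse random 32^3 bone mask with unit spacing."""
    voxels = rng.random((32, 32, 32)) < 0.05
    voxels[16, 16, 16] = True  # never empty
    return BoneMask(voxels=voxels, spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def asymmetric_image():
    """A 64x64 binary image with no flip/rotation symmetry."""
    px = np.zeros((64, 64), dtype=np.uint8)
    px[5:40, 10:20] = 1
    px[45:60, 30:55] = 1
    px[8, 50] = 1
    return ProjectedImage(pixels=px)
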