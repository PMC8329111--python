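import numpy as np
import pytest

from contourmetrics import BinaryMask


def mask_from(voxels, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(voxels=np.asarray(voxels, dtype=bool), spacing=spacing)


def box_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Solid axis-aligned box with inclusive corner lo, exclusive corner hi."""
    vox = np.zeros(shape, dtype=bool)
    vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return BinaryMask(voxels=vox, spacing=spacing)


def random_mask(rng, shape, p=0.3, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    vox = rng.random(shape) < p
    if not vox.any():
        vox[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask(voxels=vox, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
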