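import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from deltarad import ImageVolume, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sphere_mask(radius_vox: int, spacing=(1.0, 1.0, 1.0),
                     pad: int = 2) -> RoiMask:
    """Digital sphere: voxel centers within radius (in voxels) of center."""
    n = 2 * (radius_vox + pad) + 1
    c = (n - 1) / 2
    idx = np.indices((n, n, n))
    inside = ((idx - c) ** 2).sum(axis=0) <= radius_vox ** 2
    return RoiMask(inside, spacing)


def make_image(values, spacing=(1.0, 1.0, 1.0), modality="CT") -> ImageVolume:
    return ImageVolume(np.asarray(values, dtype=float), spacing,
                       modality=modality)


@pytest.fixture
def sphere_mask():
    return make_sphere_mask(10)


def random_level_roi(rng, max_shape=(6, 6, 3), max_levels=4):
    """Random small ROI of integer gray levels for oracle comparisons.

    Level 1 and the maximum drawn level are both guaranteed present so a
    unit-width fixed-bin-size discretization is the identity map.
    """
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    n_levels = int(rng.integers(2, max_levels + 1))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    values = np.zeros(shape)
    values[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    flat = np.flatnonzero(mask)
    values.flat[flat[0]] = 1
    if len(flat) > 1:
        values.flat[flat[-1]] = n_levels
    n = int(values.max())
    return values, mask, n
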