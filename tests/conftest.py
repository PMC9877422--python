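import numpy as np
import pytest
from hypothesis import settings

from wmheval import BinaryMask, VoxelGrid

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def unit_grid():
    return VoxelGrid(shape=(10, 10, 10), voxel_size=(1.0, 1.0, 1.0))


def make_grid(shape, voxel=(1.0, 1.0, 1.0)):
    return VoxelGrid(shape=tuple(shape), voxel_size=voxel)


def mask_from_array(arr, voxel=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=bool)
    return BinaryMask(grid=make_grid(arr.shape, voxel), voxels=arr)


def random_mask(rng, shape, density):
    return mask_from_array(rng.random(shape) < density)


def sphere_mask(shape, center, radius, voxel=(1.0, 1.0, 1.0)):
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return mask_from_array(d2 <= radius**2, voxel=voxel)
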