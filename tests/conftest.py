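import warnings

import numpy as np
import pytest

from peristas.synthetic import PhantomSpec, generate_case
from peristas.volume import VoxelMask


@pytest.fixture(autouse=True)
def _quiet_smote_warnings():
    # tiny test cohorts routinely trigger the documented k-reduction warning
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="minority class smaller")
        warnings.filterwarnings("ignore", message="dropping .* zero-variance")
        yield


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact phantom: 56 mm cube, 10 mm nodules, everything else default."""
    return PhantomSpec(grid_shape=(56, 56, 56), nodule_diameter_mm=10.0, diameter_sd_mm=2.0)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_case(small_spec, label=1, seed=11)


def make_mask(grid: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> VoxelMask:
    return VoxelMask(np.asarray(grid, bool), spacing)


def single_voxel_mask(shape=(11, 11, 11), spacing=(1.0, 1.0, 1.0)) -> VoxelMask:
    g = np.zeros(shape, bool)
    g[tuple(s // 2 for s in shape)] = True
    return VoxelMask(g, spacing)


def ball_mask(radius_mm: float, spacing=(1.0, 1.0, 1.0), pad: int = 3) -> VoxelMask:
    half = [int(np.ceil(radius_mm / s)) + pad for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return VoxelMask(X**2 + Y**2 + Z**2 <= radius_mm**2, spacing)
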