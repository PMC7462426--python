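import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smoothsweep.core import BrainVolume4D, VolumeGrid

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """8x8x8 grid of 2 mm voxels, random mask (~80% in-brain), 3 frames."""
    dims = (8, 8, 8)
    grid = VolumeGrid(dims, (2.0, 2.0, 2.0))
    mask = rng.random(dims) > 0.2
    data = rng.standard_normal(dims + (3,))
    return BrainVolume4D(grid, mask, data, tr=2.0)


@pytest.fixture
def full_mask_volume(rng):
    dims = (10, 10, 10)
    grid = VolumeGrid(dims, (2.0, 2.0, 2.0))
    return BrainVolume4D(grid, np.ones(dims, bool), rng.standard_normal(dims + (2,)), tr=2.0)


def brute_force_smooth(volume, fwhm, truncation_sigmas=4.0):
    """Direct per-voxel evaluation of the kernel-average definition:
    x_i <- sum_j G_i(j) x_j / sum_j G_i(j), sums over in-mask voxels
    within the (spherical) truncation radius."""
    from smoothsweep.smoothing import fwhm_to_sigma

    sigma = fwhm_to_sigma(fwhm)
    radius = truncation_sigmas * sigma
    vox = np.asarray(volume.grid.voxel_size)
    idx = np.argwhere(volume.mask)
    centers = idx * vox
    vals = volume.data[volume.mask]
    out = np.zeros_like(volume.data)
    for i in idx:
        d2 = ((centers - i * vox) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2.0 * sigma**2))
        w[d2 > radius**2] = 0.0
        out[tuple(i)] = (w[:, None] * vals).sum(axis=0) / w.sum()
    return out
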