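import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from recurrad import ImageVolume, PhantomSpec, generate_tumor_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A quiet ~8 mm tumor on a 40^3 grid, reused across feature tests."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        tumor_radii=(8.0, 7.0, 7.5),
        lobulation_amplitude=0.1,
        texture_sd=30.0,
        noise_sd=5.0,
        seed=7,
    )
    return generate_tumor_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_binned_volume(rng, max_side=6, n_levels=4):
    """Small random binned volume + mask for texture-oracle comparisons."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    binned = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    # re-index bins so masked max equals the level count actually present
    vals = binned[mask]
    binned = np.where(mask, np.searchsorted(np.unique(vals), binned) + 1, 0)
    return binned, mask


@pytest.fixture()
def sphere_mask():
    def make(radius_vox: int):
        n = 2 * radius_vox + 5
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2

    return make
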