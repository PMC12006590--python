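import numpy as np
import pytest

from spectomics.image import VoxelImage, Mask
from spectomics import phantoms as ph


def random_masked_levels(rng, shape=(5, 5, 5), n_levels=6):
    """A random level array with a random mask that has at least two voxels
    and at least one neighbouring pair."""
    while True:
        levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int64)
        mask = rng.random(shape) < 0.7
        if mask.sum() < 2:
            continue
        idx = np.argwhere(mask)
        d = np.abs(idx[:, None, :] - idx[None, :, :]).max(axis=2)
        if ((d == 1) & np.triu(np.ones_like(d, dtype=bool), 1)).any():
            return levels, mask


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_image():
    """A tiny deterministic SUV image with a box mask, for intensity tests."""
    rng = np.random.default_rng(42)
    img = VoxelImage(rng.uniform(0.2, 5.0, size=(8, 8, 8)), 1.95, unit="SUV")
    m = np.zeros((8, 8, 8), dtype=bool)
    m[2:6, 2:6, 2:6] = True
    return img, Mask(m, img.spacing, img.origin)


@pytest.fixture(scope="session")
def small_cylinder():
    """A scaled-down uniform cylinder and activity for fast simulation."""
    geom = ph.PhantomGeometry.uniform_cylinder(height=60.0, diameter=60.0,
                                               fill_volume=169.6)
    spec = ph.ActivitySpec.uniform(10.0, geom)
    return geom, spec


@pytest.fixture(scope="session")
def tc_uniform_scan():
    """One default-protocol 99mTc uniform-phantom scan at full resolution."""
    geom = ph.PhantomGeometry.uniform_cylinder()
    spec = ph.ActivitySpec.uniform(ph.UNIFORM_ACTIVITY_MBQ["tc99m"], geom)
    truth = ph.build_uniform_phantom(geom, spec, 1.95)
    model = ph.IMAGING_DEFAULTS["tc99m"]
    return geom, spec, ph.simulate_scan(truth, model, spec)
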