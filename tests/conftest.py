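import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from adcstab import ImageVolume, PhantomSpec, RoiMask, generate_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """One default phantom volume/mask pair (seeded, session-cached)."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_roi_fixture(rng, shape=(5, 5, 3), n_levels=4, p_in=0.7):
    """A small random binned volume and mask for oracle comparisons."""
    mask = rng.random(shape) < p_in
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    bins = rng.integers(1, n_levels + 1, size=shape)
    return bins, mask


@pytest.fixture
def strip_volume_mask():
    """A 1-D in-mask strip whose binned values are [1, 1, 2]."""
    vox = np.zeros((5, 3, 3))
    # bin width with 4 bins over [0, 4e-3] is 1e-3; values in bins 1,1,2
    vox[1, 1, 1] = 0.5e-3
    vox[2, 1, 1] = 0.5e-3
    vox[3, 1, 1] = 1.5e-3
    mask = np.zeros((5, 3, 3), dtype=bool)
    mask[1:4, 1, 1] = True
    return ImageVolume(vox), RoiMask(mask)
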