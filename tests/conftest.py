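import numpy as np
import pytest

from petseg.image_model import BinaryMask, VolumetricImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_region(rng):
    """A 4x4x4 image with random intensities and a random non-trivial mask."""

    def make(mask_density=0.7):
        values = rng.normal(10.0, 3.0, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) < mask_density
        # ensure at least one neighboring pair so the GLCM is defined
        mask[1, 1, 1] = mask[1, 1, 2] = True
        return VolumetricImage(values, (1.0, 1.0, 1.0)), BinaryMask(mask)

    return make
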