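import numpy as np
import pytest

from holocyte import (
    CalibrationParams,
    PhaseImage,
    example_state_models,
)
from holocyte.segmentation import object_from_mask


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def models():
    return example_state_models()


@pytest.fixture
def calib():
    return CalibrationParams(pixel_size_um=1.0)


def make_image(pixels, pixel_size_um=1.0, t=0.0, **meta):
    return PhaseImage(np.asarray(pixels, float), pixel_size_um, t=t, meta=meta)


@pytest.fixture
def square_patch():
    """10x10 square of phase 2.0 embedded in a 30x30 zero frame."""
    img = np.zeros((30, 30))
    img[10:20, 10:20] = 2.0
    mask = img > 0
    return make_image(img), object_from_mask(mask)


def random_blob_object(rng, shape=(24, 24), n_seeds=4, growth=40):
    """A random connected mask for oracle-based property tests."""
    from scipy import ndimage

    mask = np.zeros(shape, bool)
    r0 = rng.integers(4, shape[0] - 4)
    c0 = rng.integers(4, shape[1] - 4)
    mask[r0, c0] = True
    for _ in range(growth):
        cand = ndimage.binary_dilation(mask) & ~mask
        rows, cols = np.nonzero(cand)
        if len(rows) == 0:
            break
        k = rng.integers(len(rows))
        mask[rows[k], cols[k]] = True
    # keep the single largest 8-connected component
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndimage.sum(mask, lab, range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return object_from_mask(mask)
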