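import numpy as np
import pytest

from blebquant import MaskStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, shape=(48, 48), n_seeds=4, dilate=3):
    """A random connected-ish blob: union of dilated random seed points."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    rr = rng.integers(8, shape[0] - 8, size=n_seeds)
    cc = rng.integers(8, shape[1] - 8, size=n_seeds)
    mask[rr, cc] = True
    return ndimage.binary_dilation(mask, iterations=dilate)


def mask_stack(frames, **kw):
    kw.setdefault("compartment", "whole_cell")
    return MaskStack(np.asarray(frames), **kw)
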