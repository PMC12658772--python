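import numpy as np
import pytest

from cordsynth.grid import LabelMask, VolumeGrid
from cordsynth.phantom import PhantomSpec, make_phantom_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Fast noiseless phantom geometry for unit tests."""
    return PhantomSpec(shape=(48, 48, 80), noise_sd=0.0)


@pytest.fixture
def phantom_case(small_spec):
    rng = np.random.default_rng(7)
    return make_phantom_case(small_spec, rng, with_lesions=True)


def uniform_cord_volume(shape=(48, 48, 60), cord_value=100.0, spacing=0.5):
    """A volume that is uniform inside a generous central cord tube."""
    nx, ny, nz = shape
    ii = np.arange(nx)[:, None, None]
    jj = np.arange(ny)[None, :, None]
    dist = np.sqrt((ii - (nx - 1) / 2) ** 2 + (jj - (ny - 1) / 2) ** 2)
    cord = np.broadcast_to(dist <= 18, shape).copy()
    vol = np.full(shape, 20.0)
    vol[cord] = cord_value
    sp = (spacing,) * 3
    return VolumeGrid(vol, sp), LabelMask(cord, sp)


@pytest.fixture
def uniform_case():
    return uniform_cord_volume()


def embed_shape(small, full_shape, corner, spacing=(0.5, 0.5, 0.5)):
    """Place a compact shape mask into a full-size canvas, clipping at
    the canvas bounds."""
    full = np.zeros(full_shape, dtype=bool)
    ext = [min(s, f - c) for s, f, c in zip(small.shape, full_shape, corner)]
    full[corner[0]:corner[0] + ext[0], corner[1]:corner[1] + ext[1],
         corner[2]:corner[2] + ext[2]] = small.data[:ext[0], :ext[1], :ext[2]]
    return LabelMask(full, spacing)


def blob_mask(shape, lo, hi, spacing=(0.5, 0.5, 0.5)):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return LabelMask(m, spacing)
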