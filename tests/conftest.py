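import numpy as np
import pytest

from deltarad.grids import QuantizedRoi, RoiMask, VolumeGrid
from deltarad.synthdata import PhantomSpec, StentSpec, make_phantom_pair


def random_qroi(L: int, seed: int, shape=(6, 6, 6), mask_frac=0.8) -> QuantizedRoi:
    """Random quantized ROI on a small grid with a random (non-empty) mask."""
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < mask_frac
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, L + 1, size=int(mask.sum()))
    return QuantizedRoi(levels, L, (0.0, float(L)))


def constant_qroi(L: int = 8, shape=(4, 4, 4)) -> QuantizedRoi:
    levels = np.ones(shape, dtype=np.int32)
    return QuantizedRoi(levels, L, (0.0, 1.0))


@pytest.fixture
def small_phantom():
    """32 mm^3 phantom with an ~7 mm tumor; cheap enough for repeated use."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                       tumor_radii=(7.0, 6.0, 6.0), seed=7)
    return make_phantom_pair(spec)


@pytest.fixture
def stent_spec():
    return PhantomSpec(
        grid_shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0),
        tumor_radii=(10.0, 9.0, 9.0), seed=3,
        stent=StentSpec(center=(28.0, 23.5, 23.5), radius=2.0, axis=2, hu=3000.0))


def volume_from(values, spacing=(1.0, 1.0, 1.0)) -> VolumeGrid:
    return VolumeGrid(np.asarray(values, dtype=float), spacing)


def mask_all(shape) -> RoiMask:
    return RoiMask(np.ones(shape, dtype=bool))
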