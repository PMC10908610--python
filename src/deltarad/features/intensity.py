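"""First-order intensity statistics of the in-mask HU distribution."""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..grids import RoiMask, VolumeGrid
from .registry import INTENSITY_FEATURES

__all__ = ["intensity_features"]


def intensity_features(volume: VolumeGrid, mask: RoiMask) -> dict[str, float]:
    """Nine intensity features of the ROI voxels.

    Variance and standard deviation are population (ddof=0); kurtosis is excess
    kurtosis (a normal distribution scores 0); skewness and kurtosis of a
    constant ROI are 0 by convention.
    """
    mask.check_aligned(volume)
    if not mask.flags.any():
        raise ValueError("mask is empty")
    v = volume.values[mask.flags]
    if np.ptp(v) == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, fisher=True, bias=True))
    out = {
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "mean": float(v.mean()),
        "std": float(v.std(ddof=0)),
        "sum": float(v.sum()),
        "median": float(np.median(v)),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": float(v.var(ddof=0)),
    }
    assert tuple(out) == INTENSITY_FEATURES
    return out
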