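"""Radiomics feature extraction: 257 named features per scan.

``extract_all`` produces the canonical feature vector -- 9 intensity, 8
geometry, and 240 texture features (9 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM at
each of six gray-level counts) -- as a :class:`pandas.Series` with the frozen
name ordering from :mod:`deltarad.features.registry`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..grids import QuantizedRoi, RoiMask, VolumeGrid
from ..preprocess import DEFAULT_LEVELS, quantize
from .geometry import geometry_features
from .intensity import intensity_features
from .registry import TEXTURE_FAMILIES, feature_names, texture_names
from .texture import (glcm_features, glrlm_features, glszm_features,
                      ngtdm_features)

__all__ = ["extract_all", "feature_names", "texture_names", "intensity_features",
           "geometry_features", "glcm_features", "glrlm_features",
           "glszm_features", "ngtdm_features"]

_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
}


def _crop_to_roi(volume: VolumeGrid, mask: RoiMask, pad: int = 1):
    """Crop both arrays to the mask bounding box (+pad) — texture matrices only
    see in-mask voxels, so this is exact and much faster on large grids."""
    idx = np.argwhere(mask.flags)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.flags.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return volume.values[sl], mask.flags[sl]


def extract_all(volume: VolumeGrid, mask: RoiMask,
                levels=DEFAULT_LEVELS) -> pd.Series:
    """Extract the full canonical feature vector for one preprocessed scan.

    Texture features of a degenerate ROI (single voxel: no co-occurring pairs)
    are NaN rather than errors; intensity and geometry are always defined for a
    non-empty mask.  Deterministic for fixed input.
    """
    mask.check_aligned(volume)
    if not mask.flags.any():
        raise ValueError("mask is empty")
    values: dict[str, float] = {}
    try:
        for k, v in intensity_features(volume, mask).items():
            values[f"intensity.{k}"] = v
    except Exception as exc:  # pragma: no cover - context for stage failures
        raise RuntimeError(f"intensity feature extraction failed: {exc}") from exc
    try:
        for k, v in geometry_features(mask, volume.spacing).items():
            values[f"geometry.{k}"] = v
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"geometry feature extraction failed: {exc}") from exc

    vals_c, flags_c = _crop_to_roi(volume, mask)
    vol_c = VolumeGrid(vals_c, volume.spacing)
    mask_c = RoiMask(flags_c)
    degenerate = mask_c.n_voxels < 2  # no voxel pairs: texture is undefined
    quantized = {} if degenerate else {L: quantize(vol_c, mask_c, L)
                                       for L in levels}
    for family, fam_names in TEXTURE_FAMILIES:
        func = _FAMILY_FUNCS[family]
        for L in levels:
            if degenerate:
                feats = {k: float("nan") for k in fam_names}
            else:
                try:
                    feats = func(quantized[L])
                except Exception as exc:  # pragma: no cover
                    raise RuntimeError(
                        f"{family} feature extraction failed at L={L}: {exc}"
                    ) from exc
            for k, v in feats.items():
                values[f"{family}.{k}.L{L}"] = v

    names = feature_names(levels)
    assert list(values) == names
    return pd.Series(values, index=names, dtype=np.float64)


def extract_texture(q: QuantizedRoi) -> dict[str, float]:
    """All texture features of one quantized ROI (single level count)."""
    out: dict[str, float] = {}
    for family, _ in TEXTURE_FAMILIES:
        for k, v in _FAMILY_FUNCS[family](q).items():
            out[f"{family}.{k}"] = v
    return out
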