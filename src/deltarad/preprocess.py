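"""Tumor-volume preprocessing: stent exclusion, isotropic resampling, quantization.

Metal biliary stents produce extreme attenuation values that corrupt texture
statistics, so voxels whose HU falls outside a closed window (default
[-200, 500]) are removed from the ROI before feature extraction.  Volumes are
then resampled to isotropic voxels (default 1 mm) -- linear interpolation for
the image, nearest-neighbour for the mask so it stays binary -- and the window
is re-applied to catch any interpolation leakage around the stent.  Finally the
in-mask intensities are quantized to L gray levels with fixed-bin-count
(min--max) binning, which makes every downstream texture feature invariant to
positive affine HU rescalings.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import QuantizedRoi, RoiMask, VolumeGrid

__all__ = ["HU_WINDOW", "DEFAULT_LEVELS", "exclude_hu_window", "resample_isotropic",
           "quantize", "preprocess_scan"]

#: Closed HU interval retained inside the ROI; values outside are treated as
#: stent/artifact and excluded.
HU_WINDOW = (-200.0, 500.0)

#: Default gray-level counts for texture extraction.
DEFAULT_LEVELS = (8, 16, 32, 64, 128, 256)


def exclude_hu_window(volume: VolumeGrid, mask: RoiMask,
                      lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]) -> RoiMask:
    """Remove in-mask voxels whose HU lies outside the closed interval [lo, hi].

    Returns a new mask; the input mask is untouched.  Raises ``ValueError`` if
    the ROI becomes empty.
    """
    if not lo < hi:
        raise ValueError(f"require lo < hi, got ({lo}, {hi})")
    mask.check_aligned(volume)
    keep = mask.flags & (volume.values >= lo) & (volume.values <= hi)
    if not keep.any():
        raise ValueError("ROI empty after HU windowing")
    return RoiMask(keep)


def resample_isotropic(volume: VolumeGrid, mask: RoiMask,
                       target: float = 1.0) -> tuple[VolumeGrid, RoiMask]:
    """Resample volume and mask to isotropic ``target`` mm voxels.

    Linear interpolation for the image, nearest-neighbour for the mask.  If the
    input is already at the target spacing both are returned unchanged (copies).
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    mask.check_aligned(volume)
    if any(not np.isfinite(s) or s <= 0 for s in volume.spacing):
        raise ValueError(f"degenerate input spacing {volume.spacing}")
    factors = tuple(s / target for s in volume.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return (VolumeGrid(volume.values.copy(), (target,) * 3, volume.origin),
                RoiMask(mask.flags.copy()))
    out_vals = ndimage.zoom(volume.values, factors, order=1, mode="nearest",
                            grid_mode=True)
    out_mask = ndimage.zoom(mask.flags.astype(np.uint8), factors, order=0,
                            mode="nearest", grid_mode=True) > 0
    if out_mask.shape != out_vals.shape:  # pragma: no cover - zoom guarantees match
        raise RuntimeError("resampled shapes diverged")
    return (VolumeGrid(out_vals, (target,) * 3, volume.origin), RoiMask(out_mask))


def quantize(volume: VolumeGrid, mask: RoiMask, n_levels: int) -> QuantizedRoi:
    """Fixed-bin-count quantization of in-mask HU to levels 1..L.

    level = min(L, floor(L * (v - min) / (max - min)) + 1); a constant ROI maps
    every voxel to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask.check_aligned(volume)
    if not mask.flags.any():
        raise ValueError("mask is empty")
    vals = volume.values[mask.flags]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.values.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask.flags] = 1
    else:
        scaled = (volume.values[mask.flags] - vmin) / (vmax - vmin)
        lv = np.floor(n_levels * scaled).astype(np.int32) + 1
        np.minimum(lv, n_levels, out=lv)
        levels[mask.flags] = lv
    return QuantizedRoi(levels, n_levels, (vmin, vmax), spacing=volume.spacing)


def preprocess_scan(volume: VolumeGrid, mask: RoiMask,
                    lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1],
                    target: float = 1.0) -> tuple[VolumeGrid, RoiMask]:
    """Full preprocessing chain: HU window -> isotropic resample -> re-window.

    Windowing runs on the native grid first so stent voxels cannot bleed into
    neighbours through interpolation, then once more after resampling.
    """
    m = exclude_hu_window(volume, mask, lo, hi)
    vol_r, m_r = resample_isotropic(volume, m, target)
    m_r = exclude_hu_window(vol_r, m_r, lo, hi)
    return vol_r, m_r
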