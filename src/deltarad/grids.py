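"""In-memory containers for CT volumes, tumor masks, and quantized ROIs.

A :class:`VolumeGrid` holds a 3D scalar array in Hounsfield units (HU) together
with its voxel spacing in millimetres; a :class:`RoiMask` is a binary array
aligned voxel-for-voxel to a grid.  NIfTI round-trips go through nibabel with a
diagonal affine built from the spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "RoiMask", "QuantizedRoi", "load_volume", "save_volume",
           "load_mask", "save_mask"]


@dataclass
class VolumeGrid:
    """A 3D scalar volume in HU with voxel spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """Binary tumor mask aligned to a :class:`VolumeGrid`."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.flags.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())

    def check_aligned(self, volume: VolumeGrid) -> None:
        if self.flags.shape != volume.values.shape:
            raise ValueError(
                f"mask shape {self.flags.shape} != volume shape {volume.values.shape}")


@dataclass
class QuantizedRoi:
    """Gray-level quantized ROI: integer levels in 1..L inside the mask, 0 outside.

    ``window`` records the (min, max) HU range the levels were mapped from.
    """

    levels: np.ndarray
    n_levels: int
    window: tuple[float, float]
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        inside = self.levels[self.levels > 0]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return VolumeGrid(np.asanyarray(img.dataobj).astype(np.float64), spacing, origin)


def save_mask(mask: RoiMask, path, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image(mask.flags.astype(np.uint8), _affine(spacing, origin))
    nib.save(img, str(path))


def load_mask(path) -> RoiMask:
    img = nib.load(str(path))
    return RoiMask(np.asanyarray(img.dataobj) > 0)
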