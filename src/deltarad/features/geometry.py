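"""Shape features of the tumor mask.

Volume and bounding-box volume are voxel counts scaled by voxel volume.
Major/minor diameters come from the principal axes of the in-mask voxel
coordinates: for a solid ellipsoid the variance along a semi-axis ``a`` is
``a^2 / 5``, so the axis length is ``2 * sqrt(5) * sqrt(eigenvalue)`` (exact
for solid ellipsoids, which the phantoms are).  Eccentricity, elongation and
orientation are taken from the second-moment ellipse of the ROI on the axial
slice with the largest area, and the perimeter is the marching-squares contour
length on that same slice.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from ..grids import RoiMask
from .registry import GEOMETRY_FEATURES

__all__ = ["geometry_features"]

_AXIS_FACTOR = 2.0 * np.sqrt(5.0)  # solid-ellipsoid second-moment normalization


def _largest_axial_slice(flags: np.ndarray) -> int:
    areas = flags.sum(axis=(0, 1))
    return int(np.argmax(areas))


def _contour_perimeter(slice2d: np.ndarray, spacing2d) -> float:
    padded = np.pad(slice2d.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        seg = np.diff(contour, axis=0) * np.asarray(spacing2d)[None, :]
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def geometry_features(mask: RoiMask, spacing) -> dict[str, float]:
    """Eight geometry features of the ROI (distances mm, volumes mm^3)."""
    flags = mask.flags
    if not flags.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing, dtype=np.float64)
    voxvol = float(np.prod(spacing))
    n = int(flags.sum())
    volume = n * voxvol

    idx = np.argwhere(flags)
    extent = idx.max(axis=0) - idx.min(axis=0) + 1
    bbox_volume = float(np.prod(extent * spacing))

    coords = idx * spacing[None, :]
    if n > 1:
        cov = np.cov(coords.T, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        major = _AXIS_FACTOR * float(np.sqrt(eig[0]))
        minor = _AXIS_FACTOR * float(np.sqrt(eig[-1]))
    else:
        major = minor = 0.0

    z = _largest_axial_slice(flags)
    sl = flags[:, :, z]
    props = measure.regionprops(sl.astype(np.uint8), spacing=tuple(spacing[:2]))[0]
    ecc = float(props.eccentricity)
    orient = float(props.orientation)
    if props.axis_major_length > 0:
        elong = float(props.axis_minor_length / props.axis_major_length)
    else:
        elong = 0.0
    perimeter = _contour_perimeter(sl, spacing[:2])

    out = {
        "volume": volume,
        "major_diameter": major,
        "minor_diameter": minor,
        "eccentricity": ecc,
        "elongation": elong,
        "orientation": orient,
        "bbox_volume": bbox_volume,
        "perimeter": perimeter,
    }
    assert tuple(out) == GEOMETRY_FEATURES
    return out
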