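"""Canonical radiomics feature registry.

A single scan yields exactly 257 named features: 9 intensity + 8 geometry +
(9 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM) texture features at each of 6
gray-level counts = 240 texture features.  Names follow ``family.name`` for
intensity/geometry and ``family.name.L{levels}`` for texture; the ordering
below is frozen and is the column order of every feature table the package
writes.
"""

from __future__ import annotations

from ..preprocess import DEFAULT_LEVELS

INTENSITY_FEATURES = (
    "minimum", "maximum", "mean", "std", "sum", "median",
    "skewness", "kurtosis", "variance",
)

GEOMETRY_FEATURES = (
    "volume", "major_diameter", "minor_diameter", "eccentricity",
    "elongation", "orientation", "bbox_volume", "perimeter",
)

GLCM_FEATURES = (
    "energy", "contrast", "correlation", "homogeneity", "entropy",
    "dissimilarity", "variance", "sum_average", "autocorrelation",
)

GLRLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
    "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv",
)

GLSZM_FEATURES = (
    "sze", "lze", "gln", "zsn", "zp", "lgze", "hgze",
    "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

TEXTURE_FAMILIES = (
    ("glcm", GLCM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
)


def feature_names(levels=DEFAULT_LEVELS) -> list[str]:
    """Canonical ordered feature names for one scan (257 for six level counts)."""
    names = [f"intensity.{n}" for n in INTENSITY_FEATURES]
    names += [f"geometry.{n}" for n in GEOMETRY_FEATURES]
    for family, feats in TEXTURE_FAMILIES:
        for L in levels:
            names += [f"{family}.{n}.L{L}" for n in feats]
    return names


def texture_names(levels=DEFAULT_LEVELS) -> list[str]:
    """Texture-only subset of :func:`feature_names` (240 for six level counts)."""
    return [n for n in feature_names(levels)
            if n.split(".")[0] not in ("intensity", "geometry")]
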