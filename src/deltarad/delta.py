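"""Delta-radiomics construction in feature space.

A delta radiomic feature (DRF) is the post-treatment minus pre-treatment value
of a radiomic feature; the relative variant divides by the baseline value.
The BL-DRF vector concatenates the 257 baseline features with the 257 DRFs
into a 514-entry vector (names prefixed ``pre.`` / ``drf.``).  No image-space
registration or subtraction is involved: deltas live purely in feature space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["RELATIVE_EPS", "delta_subtract", "relative_delta", "concat_bl_drf"]

#: Baseline magnitudes below this are treated as zero in relative deltas; the
#: quotient is flagged missing (NaN) instead of exploding.
RELATIVE_EPS = 1e-8


def _check_names(pre: pd.Series, post: pd.Series) -> None:
    if list(pre.index) != list(post.index):
        sym = sorted(set(pre.index).symmetric_difference(post.index))
        raise ValueError(f"feature name mismatch between scans: {sym[:10]}"
                         + ("..." if len(sym) > 10 else ""))


def delta_subtract(pre: pd.Series, post: pd.Series) -> pd.Series:
    """Elementwise post - pre.  Antisymmetric under argument swap; a missing
    value in either input makes the delta missing."""
    _check_names(pre, post)
    return post - pre


def relative_delta(pre: pd.Series, post: pd.Series) -> pd.Series:
    """Elementwise (post - pre) / pre; entries with |pre| < RELATIVE_EPS are NaN."""
    _check_names(pre, post)
    denom = pre.to_numpy(dtype=float)
    num = post.to_numpy(dtype=float) - denom
    out = np.where(np.abs(denom) < RELATIVE_EPS, np.nan, num / np.where(
        np.abs(denom) < RELATIVE_EPS, 1.0, denom))
    return pd.Series(out, index=pre.index)


def concat_bl_drf(pre: pd.Series, drf: pd.Series) -> pd.Series:
    """Concatenate baseline features and DRFs into one 2N vector.

    The baseline block keeps its order with names prefixed ``pre.``; the delta
    block follows, prefixed ``drf.``.  Slicing the halves recovers the inputs.
    """
    _check_names(pre, drf)
    top = pre.copy()
    top.index = [f"pre.{n}" for n in pre.index]
    bot = drf.copy()
    bot.index = [f"drf.{n}" for n in drf.index]
    return pd.concat([top, bot])
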