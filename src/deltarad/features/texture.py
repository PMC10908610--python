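"""3D texture matrices and features: GLCM, GLRLM, GLSZM, NGTDM.

All four descriptors operate on a :class:`~deltarad.grids.QuantizedRoi` --
integer gray levels 1..L inside the mask, 0 outside -- at voxel distance 1.
Directional matrices use the 13 unique 3D direction vectors (the positive half
of the 26-neighbourhood); zones and neighbourhoods are 26-connected.

Aggregation follows the classic conventions: GLCM matrices are symmetrized,
summed over directions and normalized once (matrix-average); GLRLM features
are computed per direction and then averaged (feature-average).  GLSZM and
NGTDM are inherently direction-free.

Degenerate ROIs (a single voxel, hence no voxel pairs) yield ``NaN`` feature
values flagged by the caller rather than hard errors.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..grids import QuantizedRoi
from .registry import GLCM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES, NGTDM_FEATURES

__all__ = [
    "DIRECTIONS_3D", "glcm_matrix", "glrlm_matrices", "glszm_matrix",
    "ngtdm_table", "glcm_features", "glrlm_features", "glszm_features",
    "ngtdm_features", "COARSENESS_CAP",
]

#: The 13 unique direction vectors of the 3D 26-neighbourhood (positive half).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx == 0 and ((dy, dz) > (0, 0)))
)

#: Value returned for NGTDM coarseness when its denominator is exactly zero.
COARSENESS_CAP = 1e6


def _check_directions() -> None:
    dirs = set(DIRECTIONS_3D)
    assert len(dirs) == 13
    for d in dirs:
        assert tuple(-c for c in d) not in dirs


_check_directions()


def _shifted(a: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = a[v + d] where defined, ``fill`` elsewhere."""
    out = np.full_like(a, fill)
    src, dst = [], []
    for n, di in zip(a.shape, d):
        dst.append(slice(max(0, -di), n - max(0, di)))
        src.append(slice(max(0, di), n - max(0, -di)))
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedRoi) -> np.ndarray:
    """Direction-summed symmetric co-occurrence probabilities, shape (L, L).

    Returns the all-zero matrix when the ROI contains no voxel pair (degenerate).
    """
    L = q.n_levels
    lv = q.levels
    counts = np.zeros((L, L), dtype=np.int64)
    for d in DIRECTIONS_3D:
        nb = _shifted(lv, d)
        valid = (lv > 0) & (nb > 0)
        if not valid.any():
            continue
        i = lv[valid] - 1
        j = nb[valid] - 1
        np.add.at(counts, (i, j), 1)
    counts = counts + counts.T  # symmetrize
    total = counts.sum()
    if total == 0:
        return np.zeros((L, L), dtype=np.float64)
    return counts / total


def glrlm_matrices(q: QuantizedRoi) -> list[np.ndarray]:
    """Run-length count matrices, one (L, R_max) int array per direction.

    Row i (0-based) is gray level i+1; column j is run length j+1.  For every
    direction the voxel-conservation identity sum_ij (j+1) * M[i, j] == Nv
    holds exactly.
    """
    L = q.n_levels
    lv = q.levels
    rmax = max(int(np.ceil(np.linalg.norm(lv.shape))), 1)
    out = []
    for d in DIRECTIONS_3D:
        # cont[v]: run continues from v to v+d (same level, both in mask)
        nxt = _shifted(lv, d)
        cont = (lv > 0) & (nxt == lv) & (nxt > 0)
        # runlen[v] = number of consecutive same-level voxels from v along +d
        runlen = np.zeros(lv.shape, dtype=np.int32)
        axis = next(k for k, di in enumerate(d) if di != 0)
        step = d[axis]
        rest = tuple(di for k, di in enumerate(d) if k != axis)
        n_ax = lv.shape[axis]
        order = range(n_ax - 1, -1, -1) if step > 0 else range(n_ax)
        idx = [slice(None)] * 3
        for i in order:
            idx[axis] = i
            sl = tuple(idx)
            j = i + step
            if 0 <= j < n_ax:
                idx[axis] = j
                nxt_sl = runlen[tuple(idx)]
                idx[axis] = i
                nxt_here = _shifted(nxt_sl, rest)
            else:
                nxt_here = 0
            runlen[sl] = np.where(cont[sl], nxt_here + 1, np.where(lv[sl] > 0, 1, 0))
        # run starts: in mask and predecessor along -d is a different level
        prev = _shifted(lv, tuple(-c for c in d))
        start = (lv > 0) & (prev != lv)
        gi = lv[start] - 1
        rj = runlen[start] - 1
        mat = np.zeros((L, rmax), dtype=np.int64)
        np.add.at(mat, (gi, rj), 1)
        out.append(mat)
    return out


def glszm_matrix(q: QuantizedRoi) -> np.ndarray:
    """Gray-level size-zone count matrix, shape (L, Z_max).

    Zones are 26-connected components of equal gray level; column j is zone
    size j+1.  sum_ij (j+1) * M[i, j] == Nv exactly.
    """
    L = q.n_levels
    lv = q.levels
    nv = q.n_voxels
    struct = np.ones((3, 3, 3), dtype=bool)
    mat = np.zeros((L, max(nv, 1)), dtype=np.int64)
    for g in np.unique(lv[lv > 0]):
        lab, nlab = ndimage.label(lv == g, structure=struct)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz, cnt in zip(*np.unique(sizes, return_counts=True)):
            mat[g - 1, sz - 1] += cnt
    zmax = max(int(np.nonzero(mat.any(axis=0))[0].max()) + 1, 1) if mat.any() else 1
    return mat[:, :zmax]


def ngtdm_table(q: QuantizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference table.

    Returns ``(n_i, s_i)`` indexed by gray level 1..L (0-based arrays of length
    L): ``n_i`` counts in-mask voxels of level i with at least one in-mask
    26-neighbour, ``s_i`` sums |level - mean(in-mask neighbour levels)| over
    those voxels.
    """
    L = q.n_levels
    lv = q.levels.astype(np.float64)
    inmask = q.levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(lv * inmask, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(inmask.astype(np.float64), kernel,
                               mode="constant", cval=0.0)
    valid = inmask & (nb_cnt > 0.5)
    diff = np.zeros_like(lv)
    diff[valid] = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(q.levels[valid] - 1, minlength=L).astype(np.int64)
    s_i = np.bincount(q.levels[valid] - 1, weights=diff[valid], minlength=L)
    return n_i, s_i


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def glcm_features(q: QuantizedRoi) -> dict[str, float]:
    """Nine co-occurrence features from the direction-averaged symmetric GLCM."""
    P = glcm_matrix(q)
    if P.sum() == 0:  # degenerate: no voxel pairs
        return {name: float("nan") for name in GLCM_FEATURES}
    L = q.n_levels
    i = np.arange(1, L + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)
    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    if sigma > 0:
        correlation = float(((I - mu) * (J - mu) * P).sum() / (sigma * sigma))
    else:
        correlation = 1.0  # single-level ROI: perfectly correlated by convention
    return {
        "energy": float((P ** 2).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "correlation": correlation,
        "homogeneity": float((P / (1.0 + (I - J) ** 2)).sum()),
        "entropy": entropy,
        "dissimilarity": float((np.abs(I - J) * P).sum()),
        "variance": sigma2,
        # sum over k of k * p_{x+y}(k) collapses to 2*mu for a symmetric matrix
        "sum_average": 2.0 * mu,
        "autocorrelation": float((I * J * P).sum()),
    }


def _rlm_style_features(mat: np.ndarray, n_voxels: int,
                        names: tuple[str, ...]) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas on one count matrix.

    ``names`` supplies the family-specific feature names in canonical order
    (short-run vs small-zone emphasis etc. are the same formulas with run
    length replaced by zone size).
    """
    nr = mat.sum()
    if nr == 0:
        return {name: float("nan") for name in names}
    L, R = mat.shape
    gi = np.arange(1, L + 1, dtype=np.float64)[:, None]
    rj = np.arange(1, R + 1, dtype=np.float64)[None, :]
    m = mat.astype(np.float64)
    p = m / nr
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_g = float((p * gi).sum())
    mu_r = float((p * rj).sum())
    vals = [
        float((m / rj ** 2).sum() / nr),            # SRE / SZE
        float((m * rj ** 2).sum() / nr),            # LRE / LZE
        float((row ** 2).sum() / nr),               # GLN
        float((col ** 2).sum() / nr),               # RLN / ZSN
        float(nr / n_voxels),                       # RP / ZP
        float((m / gi ** 2).sum() / nr),            # LGRE / LGZE
        float((m * gi ** 2).sum() / nr),            # HGRE / HGZE
        float((m / (gi ** 2 * rj ** 2)).sum() / nr),  # SRLGE / SZLGE
        float((m * gi ** 2 / rj ** 2).sum() / nr),  # SRHGE / SZHGE
        float((m * rj ** 2 / gi ** 2).sum() / nr),  # LRLGE / LZLGE
        float((m * gi ** 2 * rj ** 2).sum() / nr),  # LRHGE / LZHGE
        float((p * (gi - mu_g) ** 2).sum()),        # gray-level variance
        float((p * (rj - mu_r) ** 2).sum()),        # run-length / zone-size variance
    ]
    return dict(zip(names, vals))


def glrlm_features(q: QuantizedRoi) -> dict[str, float]:
    """Thirteen run-length features, computed per direction then averaged."""
    nv = q.n_voxels
    per_dir = [_rlm_style_features(m, nv, GLRLM_FEATURES) for m in glrlm_matrices(q)]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_FEATURES}


def glszm_features(q: QuantizedRoi) -> dict[str, float]:
    """Thirteen size-zone features from the 26-connected zone matrix."""
    return _rlm_style_features(glszm_matrix(q), q.n_voxels, GLSZM_FEATURES)


def ngtdm_features(q: QuantizedRoi) -> dict[str, float]:
    """Five neighbourhood gray-tone difference features (Amadasun--King)."""
    n_i, s_i = ngtdm_table(q)
    nvc = int(n_i.sum())
    if nvc == 0:
        return {name: float("nan") for name in NGTDM_FEATURES}
    L = q.n_levels
    p_i = n_i / nvc
    lev = np.arange(1, L + 1, dtype=np.float64)
    present = p_i > 0
    ng = int(present.sum())
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ng > 1:
        ii = lev[present]
        pi = p_i[present]
        si = s_i[present]
        D2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = (float((pi[:, None] * pi[None, :] * D2).sum()) / (ng * (ng - 1))
                    * float(s_i.sum()) / nvc)
        denom_b = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = ps / denom_b if denom_b > 0 else 0.0
        num_c = (np.abs(ii[:, None] - ii[None, :])
                 * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                 / (pi[:, None] + pi[None, :]))
        complexity = float(num_c.sum()) / nvc
        ssum = float(s_i.sum())
        strength = (float(((pi[:, None] + pi[None, :]) * D2).sum()) / ssum
                    if ssum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": float(coarseness),
        "contrast": float(contrast),
        "busyness": float(busyness),
        "complexity": float(complexity),
        "strength": float(strength),
    }
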