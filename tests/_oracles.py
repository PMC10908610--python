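"""Independent brute-force oracles used to verify the vectorized texture code.

Everything here is written as plain nested loops straight from the textbook
definitions -- no shared code with the package implementation -- so agreement
is meaningful.  Only ever run on tiny ROIs.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

OFFSETS_26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]

DIRECTIONS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)
                 or (d[0] == 0 and (d[1], d[2]) > (0, 0))]


def _in(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


def oracle_glcm_matrix(levels: np.ndarray, L: int) -> np.ndarray:
    """Symmetric direction-summed co-occurrence probabilities by pair counting."""
    shape = levels.shape
    counts = np.zeros((L, L))
    for v in np.ndindex(shape):
        if levels[v] == 0:
            continue
        for d in OFFSETS_26:  # both directions == symmetrized half-set
            w = tuple(a + b for a, b in zip(v, d))
            if _in(shape, w) and levels[w] > 0:
                counts[levels[v] - 1, levels[w] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def oracle_glcm_features(levels: np.ndarray, L: int) -> dict:
    P = oracle_glcm_matrix(levels, L)
    feats = {}
    energy = contrast = homo = entropy = dissim = autoc = sumavg = 0.0
    mu = 0.0
    for i in range(L):
        for j in range(L):
            mu += (i + 1) * P[i, j]
    var = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            energy += p * p
            contrast += (i - j) ** 2 * p
            homo += p / (1 + (i - j) ** 2)
            dissim += abs(i - j) * p
            autoc += (i + 1) * (j + 1) * p
            sumavg += ((i + 1) + (j + 1)) * p
            if p > 0:
                entropy -= p * math.log2(p)
            var += ((i + 1) - mu) ** 2 * p
    sig2 = 0.0
    for i in range(L):
        pi = P[i, :].sum()
        sig2 += ((i + 1) - mu) ** 2 * pi
    corr = 0.0
    if sig2 > 0:
        for i in range(L):
            for j in range(L):
                corr += ((i + 1) - mu) * ((j + 1) - mu) * P[i, j]
        corr /= sig2
    else:
        corr = 1.0
    feats.update(energy=energy, contrast=contrast, correlation=corr,
                 homogeneity=homo, entropy=entropy, dissimilarity=dissim,
                 variance=sig2, sum_average=sumavg, autocorrelation=autoc)
    return feats


def oracle_glrlm_matrix(levels: np.ndarray, L: int, d) -> np.ndarray:
    """Run-length counts for one direction by explicit run walking."""
    shape = levels.shape
    runs = []
    for v in np.ndindex(shape):
        g = levels[v]
        if g == 0:
            continue
        prev = tuple(a - b for a, b in zip(v, d))
        if _in(shape, prev) and levels[prev] == g:
            continue  # not a run start
        length = 1
        w = tuple(a + b for a, b in zip(v, d))
        while _in(shape, w) and levels[w] == g:
            length += 1
            w = tuple(a + b for a, b in zip(w, d))
        runs.append((g, length))
    rmax = max((r for _, r in runs), default=1)
    mat = np.zeros((L, rmax))
    for g, r in runs:
        mat[g - 1, r - 1] += 1
    return mat


def _rlm_features_from_matrix(mat: np.ndarray, n_voxels: int, names) -> dict:
    L, R = mat.shape
    nr = mat.sum()
    vals = dict.fromkeys(names, math.nan)
    if nr == 0:
        return vals
    sre = lre = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
    mu_g = mu_r = 0.0
    for i in range(L):
        for j in range(R):
            m = mat[i, j]
            g, r = i + 1, j + 1
            sre += m / r ** 2
            lre += m * r ** 2
            lgre += m / g ** 2
            hgre += m * g ** 2
            srlge += m / (g ** 2 * r ** 2)
            srhge += m * g ** 2 / r ** 2
            lrlge += m * r ** 2 / g ** 2
            lrhge += m * g ** 2 * r ** 2
            mu_g += m / nr * g
            mu_r += m / nr * r
    glv = rlv = 0.0
    for i in range(L):
        for j in range(R):
            p = mat[i, j] / nr
            glv += p * ((i + 1) - mu_g) ** 2
            rlv += p * ((j + 1) - mu_r) ** 2
    gln = sum(mat[i, :].sum() ** 2 for i in range(L)) / nr
    rln = sum(mat[:, j].sum() ** 2 for j in range(R)) / nr
    ordered = [sre / nr, lre / nr, gln, rln, nr / n_voxels, lgre / nr,
               hgre / nr, srlge / nr, srhge / nr, lrlge / nr, lrhge / nr,
               glv, rlv]
    return dict(zip(names, ordered))


def oracle_glrlm_features(levels: np.ndarray, L: int, names) -> dict:
    n_voxels = int((levels > 0).sum())
    per_dir = [_rlm_features_from_matrix(oracle_glrlm_matrix(levels, L, d),
                                         n_voxels, names)
               for d in DIRECTIONS_13]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in names}


def oracle_glszm_matrix(levels: np.ndarray, L: int) -> np.ndarray:
    """Size-zone counts via breadth-first flood fill, 26-connected."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in np.ndindex(shape):
        if levels[v] == 0 or seen[v]:
            continue
        g = levels[v]
        size = 0
        queue = deque([v])
        seen[v] = True
        while queue:
            u = queue.popleft()
            size += 1
            for d in OFFSETS_26:
                w = tuple(a + b for a, b in zip(u, d))
                if _in(shape, w) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    queue.append(w)
        zones.append((g, size))
    zmax = max((s for _, s in zones), default=1)
    mat = np.zeros((L, zmax))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def oracle_glszm_features(levels: np.ndarray, L: int, names) -> dict:
    n_voxels = int((levels > 0).sum())
    return _rlm_features_from_matrix(oracle_glszm_matrix(levels, L), n_voxels, names)


def oracle_ngtdm_table(levels: np.ndarray, L: int):
    shape = levels.shape
    n_i = np.zeros(L)
    s_i = np.zeros(L)
    for v in np.ndindex(shape):
        g = levels[v]
        if g == 0:
            continue
        nb = []
        for d in OFFSETS_26:
            w = tuple(a + b for a, b in zip(v, d))
            if _in(shape, w) and levels[w] > 0:
                nb.append(levels[w])
        if nb:
            n_i[g - 1] += 1
            s_i[g - 1] += abs(g - sum(nb) / len(nb))
    return n_i, s_i


def oracle_ngtdm_features(levels: np.ndarray, L: int, cap=1e6) -> dict:
    n_i, s_i = oracle_ngtdm_table(levels, L)
    nvc = n_i.sum()
    p_i = n_i / nvc
    present = [i for i in range(L) if p_i[i] > 0]
    ng = len(present)
    ps = sum(p_i[i] * s_i[i] for i in range(L))
    coarseness = 1.0 / ps if ps > 0 else cap
    if ng > 1:
        contrast = 0.0
        for i in present:
            for j in present:
                contrast += p_i[i] * p_i[j] * (i - j) ** 2
        contrast = contrast / (ng * (ng - 1)) * s_i.sum() / nvc
        denom = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                    for i in present for j in present)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                         / (p_i[i] + p_i[j])
                         for i in present for j in present) / nvc
        ssum = s_i.sum()
        strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                        for i in present for j in present) / ssum
                    if ssum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return dict(coarseness=coarseness, contrast=contrast, busyness=busyness,
                complexity=complexity, strength=strength)


# ---------------------------------------------------------------------------
# Pair-counting oracles for ranking metrics
# ---------------------------------------------------------------------------

def oracle_concordance(time, event, scores) -> float:
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def oracle_auc(labels, scores) -> float:
    num = den = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == 1 and labels[j] == 0:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den
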