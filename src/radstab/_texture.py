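"""2-D texture-matrix engines: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

Each function takes a discretized 2-D slice (integer gray levels >= 1
inside the ROI, 0 outside) and returns a dict of named feature values.
Formulas follow the IBSI definitions with the conventions used by the
common open-source radiomics engines:

* GLCM: symmetric co-occurrence, distance 1, the four 2-D directions,
  feature values averaged over directions;
* GLRLM: the four 2-D directions, averaged;
* GLSZM: zones are 8-connected components of constant gray level;
* GLDM: dependence size k = 1 + number of 8-neighbours within the ROI whose
  level differs by at most ``alpha`` (the +1 counts the centre voxel and
  keeps k >= 1);
* NGTDM: 8-neighbourhood averages restricted to ROI voxels.

Features undefined on a slice (e.g. a single-voxel ROI has no co-occurring
pairs) are returned as NaN, never silently as zero.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from skimage.measure import label as cc_label

_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _nan_dict(names) -> Dict[str, float]:
    return {n: float("nan") for n in names}


# --------------------------------------------------------------------------
# GLCM

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)


def _glcm_single(P: np.ndarray, lv: np.ndarray, n_levels: int) -> Dict[str, float]:
    """Features of one normalized symmetric GLCM; ``lv`` holds the actual
    gray values of the matrix rows/columns."""
    ii = lv[:, None].astype(float)
    jj = lv[None, :].astype(float)
    px = P.sum(axis=1)
    mu = float(np.sum(px * lv))
    sigma2 = float(np.sum(px * (lv - mu) ** 2))

    ksum = (lv[:, None] + lv[None, :]).astype(int)
    kdiff = np.abs(lv[:, None] - lv[None, :]).astype(int)
    pxy_sum = np.bincount(ksum.ravel(), weights=P.ravel())
    pxy_diff = np.bincount(kdiff.ravel(), weights=P.ravel())
    k_sum = np.arange(len(pxy_sum), dtype=float)
    k_diff = np.arange(len(pxy_diff), dtype=float)

    nz = P > 0
    eps_log = P[nz]
    hxy = -float(np.sum(eps_log * np.log2(eps_log)))
    pxi = px[:, None] * px[None, :]
    hxy1 = -float(np.sum(P[nz] * np.log2(pxi[nz])))
    nzm = pxi > 0
    hxy2 = -float(np.sum(pxi[nzm] * np.log2(pxi[nzm])))
    pnz = px[px > 0]
    hx = -float(np.sum(pnz * np.log2(pnz)))

    da = float(np.sum(pxy_diff * k_diff))
    snz = pxy_sum > 0
    dnz = pxy_diff > 0

    out: Dict[str, float] = {}
    out["Autocorrelation"] = float(np.sum(P * ii * jj))
    out["JointAverage"] = mu
    cen = ii + jj - 2.0 * mu
    out["ClusterProminence"] = float(np.sum(P * cen**4))
    out["ClusterShade"] = float(np.sum(P * cen**3))
    out["ClusterTendency"] = float(np.sum(P * cen**2))
    out["Contrast"] = float(np.sum(P * (ii - jj) ** 2))
    out["Correlation"] = (
        (out["Autocorrelation"] - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    )
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -float(np.sum(pxy_diff[dnz] * np.log2(pxy_diff[dnz])))
    out["DifferenceVariance"] = float(np.sum(pxy_diff * (k_diff - da) ** 2))
    out["JointEnergy"] = float(np.sum(P**2))
    out["JointEntropy"] = hxy
    out["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    out["Idm"] = float(np.sum(P / (1.0 + (ii - jj) ** 2)))
    out["Idmn"] = float(np.sum(P / (1.0 + ((ii - jj) / n_levels) ** 2)))
    out["Id"] = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    out["Idn"] = float(np.sum(P / (1.0 + np.abs(ii - jj) / n_levels)))
    off = (ii != jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(off, P / np.where(off, (ii - jj) ** 2, 1.0), 0.0)
    out["InverseVariance"] = float(np.sum(inv))
    out["MaximumProbability"] = float(P.max())
    out["SumEntropy"] = -float(np.sum(pxy_sum[snz] * np.log2(pxy_sum[snz])))
    out["SumSquares"] = sigma2
    return out


def glcm_features(disc: np.ndarray) -> Dict[str, float]:
    roi = disc > 0
    levels = np.unique(disc[roi])
    if levels.size == 0:
        return _nan_dict(GLCM_NAMES)
    index = np.full(int(levels.max()) + 1, -1, dtype=int)
    index[levels] = np.arange(levels.size)
    per_dir = []
    for dy, dx in _GLCM_OFFSETS:
        h, w = disc.shape
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        a = disc[y0:y1, x0:x1]
        b = disc[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        ai = index[a[ok]]
        bi = index[b[ok]]
        M = np.zeros((levels.size, levels.size))
        np.add.at(M, (ai, bi), 1.0)
        M = M + M.T  # symmetric
        per_dir.append(_glcm_single(M / M.sum(), levels, n_levels=levels.size))
    if not per_dir:
        return _nan_dict(GLCM_NAMES)
    return {n: float(np.mean([d[n] for d in per_dir])) for n in GLCM_NAMES}


# --------------------------------------------------------------------------
# GLRLM

GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def _runs_in_line(line: np.ndarray):
    """Yield (level, run_length) for maximal runs of nonzero equal values."""
    n = len(line)
    start = 0
    while start < n:
        v = line[start]
        end = start + 1
        while end < n and line[end] == v:
            end += 1
        if v > 0:
            yield int(v), end - start
        start = end


def _lines(disc: np.ndarray, direction: int):
    if direction == 0:  # horizontal
        yield from disc
    elif direction == 1:  # vertical
        yield from disc.T
    elif direction == 2:  # main diagonals
        h, w = disc.shape
        for off in range(-h + 1, w):
            yield np.diagonal(disc, offset=off)
    else:  # anti-diagonals
        fl = np.fliplr(disc)
        h, w = fl.shape
        for off in range(-h + 1, w):
            yield np.diagonal(fl, offset=off)


def _rl_features(P: np.ndarray, lv: np.ndarray, np_voxels: int) -> Dict[str, float]:
    nr = P.sum()
    p = P / nr
    rr = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    ii = lv[:, None].astype(float)
    pg = P.sum(axis=1)  # per gray level
    pr = P.sum(axis=0)  # per run length
    mu_i = float(np.sum(p * ii))
    mu_r = float(np.sum(p * rr))
    pnz = p[p > 0]
    return {
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nr**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(P * ii**2) / nr),
        "LongRunEmphasis": float(np.sum(P * rr**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 * rr**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(P * rr**2 / ii**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(P / ii**2) / nr),
        "RunEntropy": -float(np.sum(pnz * np.log2(pnz))),
        "RunLengthNonUniformity": float(np.sum(pr**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pr**2) / nr**2),
        "RunPercentage": float(nr / np_voxels),
        "RunVariance": float(np.sum(p * (rr - mu_r) ** 2)),
        "ShortRunEmphasis": float(np.sum(P / rr**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 / rr**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * rr**2)) / nr),
    }


def glrlm_features(disc: np.ndarray) -> Dict[str, float]:
    roi = disc > 0
    levels = np.unique(disc[roi])
    np_voxels = int(roi.sum())
    if levels.size == 0:
        return _nan_dict(GLRLM_NAMES)
    index = {int(v): k for k, v in enumerate(levels)}
    max_run = max(disc.shape)
    per_dir = []
    for direction in range(4):
        P = np.zeros((levels.size, max_run))
        found = False
        for line in _lines(disc, direction):
            for v, r in _runs_in_line(np.asarray(line)):
                P[index[v], r - 1] += 1.0
                found = True
        if found:
            per_dir.append(_rl_features(P, levels, np_voxels))
    if not per_dir:
        return _nan_dict(GLRLM_NAMES)
    return {n: float(np.mean([d[n] for d in per_dir])) for n in GLRLM_NAMES}


# --------------------------------------------------------------------------
# GLSZM

GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)


def glszm_features(disc: np.ndarray) -> Dict[str, float]:
    roi = disc > 0
    levels = np.unique(disc[roi])
    np_voxels = int(roi.sum())
    if levels.size == 0:
        return _nan_dict(GLSZM_NAMES)
    zones = []  # (level_index, size)
    for k, v in enumerate(levels):
        lab, n = cc_label(disc == v, connectivity=2, return_num=True)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((k, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((levels.size, max_size))
    for k, s in zones:
        P[k, s - 1] += 1.0
    nz = P.sum()
    p = P / nz
    ss = np.arange(1, max_size + 1, dtype=float)[None, :]
    ii = levels[:, None].astype(float)
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float(np.sum(p * ii))
    mu_s = float(np.sum(p * ss))
    pnz = p[p > 0]
    return {
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(P * ii**2) / nz),
        "LargeAreaEmphasis": float(np.sum(P * ss**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 * ss**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(P * ss**2 / ii**2) / nz),
        "LowGrayLevelZoneEmphasis": float(np.sum(P / ii**2) / nz),
        "SizeZoneNonUniformity": float(np.sum(ps**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2) / nz**2),
        "SmallAreaEmphasis": float(np.sum(P / ss**2) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ss**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ss**2)) / nz),
        "ZoneEntropy": -float(np.sum(pnz * np.log2(pnz))),
        "ZonePercentage": float(nz / np_voxels),
        "ZoneVariance": float(np.sum(p * (ss - mu_s) ** 2)),
    }


# --------------------------------------------------------------------------
# GLDM / NGTDM share the 8-neighbourhood

_NEIGHBOURS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def _shift_pairs(disc: np.ndarray):
    """For each 8-neighbour offset yield (centre, neighbour, both-valid)."""
    h, w = disc.shape
    for dy, dx in _NEIGHBOURS:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        c = np.zeros_like(disc)
        nb = np.zeros_like(disc)
        c[y0:y1, x0:x1] = disc[y0:y1, x0:x1]
        nb[y0:y1, x0:x1] = disc[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        yield c, nb


GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def gldm_features(disc: np.ndarray, alpha: int = 0) -> Dict[str, float]:
    roi = disc > 0
    levels = np.unique(disc[roi])
    if levels.size == 0:
        return _nan_dict(GLDM_NAMES)
    dep = np.zeros(disc.shape, dtype=int)
    for c, nb in _shift_pairs(disc):
        dep += ((c > 0) & (nb > 0) & (np.abs(c - nb) <= alpha)).astype(int)
    k = dep[roi] + 1  # centre voxel counts itself
    g = disc[roi]
    index = np.full(int(levels.max()) + 1, -1, dtype=int)
    index[levels] = np.arange(levels.size)
    P = np.zeros((levels.size, int(k.max())))
    np.add.at(P, (index[g], k - 1), 1.0)
    nz = P.sum()
    p = P / nz
    kk = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    ii = levels[:, None].astype(float)
    pg = P.sum(axis=1)
    pk = P.sum(axis=0)
    mu_i = float(np.sum(p * ii))
    mu_k = float(np.sum(p * kk))
    pnz = p[p > 0]
    return {
        "DependenceEntropy": -float(np.sum(pnz * np.log2(pnz))),
        "DependenceNonUniformity": float(np.sum(pk**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pk**2) / nz**2),
        "DependenceVariance": float(np.sum(p * (kk - mu_k) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(P * ii**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(P * kk**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 * kk**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * kk**2 / ii**2) / nz),
        "LowGrayLevelEmphasis": float(np.sum(P / ii**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(P / kk**2) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 / kk**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * kk**2)) / nz),
    }


NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def ngtdm_features(disc: np.ndarray) -> Dict[str, float]:
    roi = disc > 0
    levels = np.unique(disc[roi])
    if levels.size == 0:
        return _nan_dict(NGTDM_NAMES)
    nbr_sum = np.zeros(disc.shape, dtype=float)
    nbr_cnt = np.zeros(disc.shape, dtype=int)
    for c, nb in _shift_pairs(disc):
        valid = (c > 0) & (nb > 0)
        nbr_sum += np.where(valid, nb, 0.0)
        nbr_cnt += valid.astype(int)
    valid = roi & (nbr_cnt > 0)
    if not valid.any():
        return _nan_dict(NGTDM_NAMES)
    A = nbr_sum[valid] / nbr_cnt[valid]
    g = disc[valid].astype(float)
    nvp = int(valid.sum())
    iv = levels.astype(float)
    n_i = np.array([np.sum(g == v) for v in iv], dtype=float)
    s_i = np.array([np.sum(np.abs(v - A[g == v])) for v in iv])
    p_i = n_i / nvp
    pos = p_i > 0
    ngp = int(pos.sum())
    ii = iv[:, None]
    jj = iv[None, :]
    pp_i = p_i[:, None]
    pp_j = p_i[None, :]
    pair = pos[:, None] & pos[None, :]

    out: Dict[str, float] = {}
    coarse_den = float(np.sum(p_i * s_i))
    out["Coarseness"] = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        out["Contrast"] = float(
            np.sum(pp_i * pp_j * (ii - jj) ** 2) / (ngp * (ngp - 1)) * np.sum(s_i) / nvp
        )
    else:
        out["Contrast"] = 0.0
    busy_den = float(np.sum(np.abs((ii * pp_i - jj * pp_j))[pair]))
    out["Busyness"] = coarse_den / busy_den if busy_den > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        comp = np.abs(ii - jj) * (pp_i * s_i[:, None] + pp_j * s_i[None, :]) / (pp_i + pp_j)
    out["Complexity"] = float(np.sum(np.where(pair, comp, 0.0)) / nvp)
    s_sum = float(np.sum(s_i))
    out["Strength"] = (
        float(np.sum(((pp_i + pp_j) * (ii - jj) ** 2)[pair])) / s_sum if s_sum > 0 else 0.0
    )
    return out
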