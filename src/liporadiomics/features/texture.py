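"""Texture-matrix families over discretized gray levels.

Implements the five classical 3D texture families on an ROI of integer
gray levels: gray-level co-occurrence (GLCM, 24 features), run length
(GLRLM, 16), size zone (GLSZM, 16), dependence (GLDM, 14) and neighboring
gray-tone difference (NGTDM, 5).  Conventions:

* GLCM/GLRLM use the 13 unique distance-1 directions of the 26-connected
  3D neighborhood; co-occurrences are symmetric; features are computed per
  direction on the normalized matrix and averaged arithmetically.
* GLSZM zones and GLDM/NGTDM neighborhoods are 26-connected.
* GLDM dependence counts 26-neighbors whose level differs from the center
  by at most ``alpha`` (default 0); the dependence *size* used in the
  feature formulas counts the center voxel as well, so an isolated voxel
  has dependence size 1 and all size-weighted sums stay finite.
* Logarithms are base 2 with a machine-epsilon guard, so empty histogram
  cells contribute zero entropy.

All functions accept a full-grid level array (0 outside the ROI) plus the
boolean ROI mask and internally crop to the ROI bounding box.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

# 13 unique direction offsets of the 26-neighborhood (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class UndefinedTextureError(ValueError):
    """Raised when an ROI cannot support a texture family (e.g. no pairs)."""


def _crop(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return np.asarray(levels)[sl], mask[sl]


def _offset_slices(shape, offset):
    """Slices (src, dst) so arr[dst] sits at arr[src] + offset."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def glcm_matrices(levels, roi_mask, n_levels: int) -> list[np.ndarray]:
    """Symmetric distance-1 co-occurrence counts, one matrix per direction."""
    lvl, m = _crop(levels, roi_mask)
    if m.sum() < 2:
        raise UndefinedTextureError("GLCM requires at least 2 ROI voxels")
    mats = []
    li = lvl - 1  # 0-based
    for off in DIRECTIONS_13:
        src, dst = _offset_slices(lvl.shape, off)
        valid = m[src] & m[dst]
        a = li[src][valid]
        b = li[dst][valid]
        counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        c = counts.reshape(n_levels, n_levels).astype(float)
        mats.append(c + c.T)
    return mats


def glrlm_matrices(levels, roi_mask, n_levels: int) -> list[np.ndarray]:
    """Run-length count matrices (gray level x run length), per direction."""
    lvl, m = _crop(levels, roi_mask)
    max_len = int(np.ceil(np.sqrt(sum(n * n for n in lvl.shape)))) + 1
    mats = []
    for off in DIRECTIONS_13:
        src, dst = _offset_slices(lvl.shape, off)
        same = np.zeros(lvl.shape, dtype=bool)  # level(v) == level(v + off), both in ROI
        same[src] = m[src] & m[dst] & (lvl[src] == lvl[dst])
        # forward run extent: F(v) = 1 + F(v + off) where same(v)
        f = m.astype(np.int64)
        while True:
            nxt = f.copy()
            nxt[src][same[src]] = f[dst][same[src]] + 1
            if np.array_equal(nxt, f):
                break
            f = nxt
        # run starts: no identical in-ROI predecessor
        prev_same = np.zeros(lvl.shape, dtype=bool)
        prev_same[dst] = same[src]
        starts = m & ~prev_same
        g = lvl[starts] - 1
        r = f[starts] - 1
        counts = np.bincount(g * max_len + r, minlength=n_levels * max_len)
        p = counts.reshape(n_levels, max_len).astype(float)
        used = int(np.max(np.nonzero(p.sum(axis=0))[0])) + 1 if p.any() else 1
        mats.append(p[:, :used])
    return mats


def glszm_matrix(levels, roi_mask, n_levels: int) -> np.ndarray:
    """Size-zone counts (gray level x zone size), 26-connected zones."""
    lvl, m = _crop(levels, roi_mask)
    zone_counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for g in range(1, n_levels + 1):
        binary = (lvl == g) & m
        if not binary.any():
            continue
        lab, n_zones = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zone_counts[(g, int(s))] = zone_counts.get((g, int(s)), 0) + 1
            max_size = max(max_size, int(s))
    mat = np.zeros((n_levels, max_size), dtype=float)
    for (g, s), c in zone_counts.items():
        mat[g - 1, s - 1] = c
    return mat


def gldm_matrix(levels, roi_mask, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts (gray level x neighbor-dependence 0..26).

    Column ``d`` counts ROI voxels with exactly ``d`` 26-neighbors inside
    the ROI whose gray level differs from the center by at most ``alpha``.
    """
    lvl, m = _crop(levels, roi_mask)
    dep = np.zeros(lvl.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        for o in (off, tuple(-x for x in off)):
            src, dst = _offset_slices(lvl.shape, o)
            ok = m[src] & m[dst] & (np.abs(lvl[src] - lvl[dst]) <= alpha)
            dep[src] += ok
    g = lvl[m] - 1
    d = dep[m]
    counts = np.bincount(g * 27 + d, minlength=n_levels * 27)
    mat = counts.reshape(n_levels, 27).astype(float)
    used = int(np.max(np.nonzero(mat.sum(axis=0))[0])) + 1
    return mat[:, :used]


def ngtdm_table(levels, roi_mask, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level voxel counts n_i and summed gray-tone differences s_i.

    s_i sums |i - A(v)| over ROI voxels of level i, where A(v) is the mean
    level of the in-ROI 26-neighbors of v; voxels with no in-ROI neighbor
    are excluded (their count does not enter n_i).
    """
    lvl, m = _crop(levels, roi_mask)
    nb_sum = np.zeros(lvl.shape, dtype=np.int64)
    nb_cnt = np.zeros(lvl.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        for o in (off, tuple(-x for x in off)):
            src, dst = _offset_slices(lvl.shape, o)
            ok = m[src] & m[dst]
            nb_sum[src] += np.where(ok, lvl[dst], 0)
            nb_cnt[src] += ok
    valid = m & (nb_cnt > 0)
    g = lvl[valid]
    diff = np.abs(g - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(g - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(g - 1, weights=diff, minlength=n_levels)
    return n_i, s_i


# ---------------------------------------------------------------------------
# Feature formulas
# ---------------------------------------------------------------------------

def glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    """The 24 GLCM features from one direction's symmetric count matrix."""
    total = counts.sum()
    if total == 0:
        raise UndefinedTextureError("no co-occurring pairs in this direction")
    p = counts / total
    ng = p.shape[0]
    g = np.arange(1, ng + 1, dtype=float)
    i = g[:, None]
    j = g[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * g).sum())
    mu_y = float((py * g).sum())
    var_x = float((px * (g - mu_x) ** 2).sum())
    var_y = float((py * (g - mu_y) ** 2).sum())

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    ii, jj = np.indices(p.shape)
    np.add.at(p_sum, ii + jj, p)
    np.add.at(p_diff, np.abs(ii - jj), p)

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    hxy = float(-(p * np.log2(p + _EPS)).sum())
    pxpy = px[:, None] * py[None, :]
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((p * i * j).sum())
    out["JointAverage"] = mu_x
    out["ClusterProminence"] = float((p * (i + j - mu_x - mu_y) ** 4).sum())
    out["ClusterShade"] = float((p * (i + j - mu_x - mu_y) ** 3).sum())
    out["ClusterTendency"] = float((p * (i + j - mu_x - mu_y) ** 2).sum())
    out["Contrast"] = float((p * (i - j) ** 2).sum())
    sd = np.sqrt(var_x * var_y)
    out["Correlation"] = (
        1.0 if sd == 0 else float(((p * i * j).sum() - mu_x * mu_y) / sd)
    )
    da = float((p_diff * k_diff).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = float(-(p_diff * np.log2(p_diff + _EPS)).sum())
    out["DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    out["JointEnergy"] = float((p**2).sum())
    out["JointEntropy"] = hxy
    div = max(hx, hy)
    out["Imc1"] = 0.0 if div == 0 else float((hxy - hxy1) / div)
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    out["Idm"] = float((p / (1.0 + (i - j) ** 2)).sum())
    out["Idmn"] = float((p / (1.0 + (i - j) ** 2 / ng**2)).sum())
    out["Id"] = float((p / (1.0 + np.abs(i - j))).sum())
    out["Idn"] = float((p / (1.0 + np.abs(i - j) / ng)).sum())
    off_diag = ii != jj
    with np.errstate(divide="ignore", invalid="ignore"):
        iv = p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2
    out["InverseVariance"] = float(iv.sum())
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((p_sum * k_sum).sum())
    out["SumEntropy"] = float(-(p_sum * np.log2(p_sum + _EPS)).sum())
    out["SumSquares"] = float((p * (i - mu_x) ** 2).sum())
    out["MCC"] = _glcm_mcc(p, px, py)
    return out


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    nz = px > 0
    if nz.sum() <= 1:
        return 1.0
    psub = p[np.ix_(nz, nz)]
    pxs = px[nz]
    pys = py[nz]
    q = (psub[:, None, :] * psub[None, :, :] / (pxs[:, None, None] * pys[None, None, :])).sum(
        axis=2
    )
    eig = np.sort(np.real(np.linalg.eigvals(q)))
    return float(np.sqrt(max(0.0, eig[-2])))


def _row_col_stats(mat: np.ndarray):
    total = mat.sum()
    p = mat / total
    ng, nc = p.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nc + 1, dtype=float)[None, :]
    return total, p, i, j


def glrlm_features_single(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 GLRLM features from one direction's run-length matrix."""
    nr, p, i, j = _row_col_stats(mat)
    pg = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    return {
        "ShortRunEmphasis": float((p / j**2).sum()),
        "LongRunEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "RunLengthNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr**2).sum()),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (j - mu_j) ** 2).sum()),
        "RunEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelRunEmphasis": float((p / i**2).sum()),
        "HighGrayLevelRunEmphasis": float((p * i**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 GLSZM features (zone analogues of the run-length set)."""
    nz, p, i, s = _row_col_stats(mat)
    pg = p.sum(axis=1, keepdims=True)
    ps = p.sum(axis=0, keepdims=True)
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    return {
        "SmallAreaEmphasis": float((p / s**2).sum()),
        "LargeAreaEmphasis": float((p * s**2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "SizeZoneNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum()),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelZoneEmphasis": float((p / i**2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * i**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (i**2 * s**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * i**2 / s**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * s**2 / i**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * i**2 * s**2).sum()),
    }


def gldm_features(mat: np.ndarray) -> dict[str, float]:
    """The 14 GLDM features; dependence size j counts the center voxel."""
    nd, p, i, j0 = _row_col_stats(mat)
    j = j0  # columns are dependence sizes 1..(max neighbors + 1) after shift
    pg = p.sum(axis=1, keepdims=True)
    pd = p.sum(axis=0, keepdims=True)
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    return {
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nd),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nd),
        "DependenceNonUniformityNormalized": float((pd**2).sum()),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    """The 5 NGTDM features from per-level counts and gray-tone differences."""
    n_total = n_i.sum()
    if n_total == 0:
        raise UndefinedTextureError("NGTDM has no voxels with in-ROI neighbors")
    p_i = n_i / n_total
    g = np.arange(1, len(n_i) + 1, dtype=float)
    nz = p_i > 0
    ngp = int(nz.sum())

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1e6 if coarse_den == 0 else 1.0 / coarse_den

    if ngp == 1:
        contrast = 0.0
    else:
        pij = p_i[nz][:, None] * p_i[nz][None, :]
        dij2 = (g[nz][:, None] - g[nz][None, :]) ** 2
        contrast = float((pij * dij2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_total))

    busy_den = float(
        np.abs(
            (g[nz] * p_i[nz])[:, None] - (g[nz] * p_i[nz])[None, :]
        ).sum()
    )
    busyness = 0.0 if busy_den == 0 else float((p_i * s_i).sum() / busy_den)

    if ngp == 1:
        complexity = 0.0
        strength = 0.0
    else:
        gi = g[nz][:, None]
        gj = g[nz][None, :]
        pi = p_i[nz][:, None]
        pj = p_i[nz][None, :]
        si = s_i[nz][:, None]
        sj = s_i[nz][None, :]
        complexity = float(
            (np.abs(gi - gj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_total
        )
        s_sum = float(s_i.sum())
        strength = 0.0 if s_sum == 0 else float(
            ((pi + pj) * (gi - gj) ** 2).sum() / s_sum
        )

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# Family entry points (averaged over directions where applicable)
# ---------------------------------------------------------------------------

def _average(dicts: list[dict[str, float]]) -> dict[str, float]:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def glcm(levels, roi_mask, n_levels: int) -> dict[str, float]:
    """24 GLCM features, averaged over the 13 symmetric directions."""
    mats = glcm_matrices(levels, roi_mask, n_levels)
    per_dir = [glcm_features_single(m) for m in mats if m.sum() > 0]
    if not per_dir:
        raise UndefinedTextureError("ROI has no neighboring voxel pairs")
    return _average(per_dir)


def glrlm(levels, roi_mask, n_levels: int) -> dict[str, float]:
    """16 GLRLM features, averaged over the 13 directions."""
    n_vox = int(np.asarray(roi_mask, dtype=bool).sum())
    mats = glrlm_matrices(levels, roi_mask, n_levels)
    return _average([glrlm_features_single(m, n_vox) for m in mats])


def glszm(levels, roi_mask, n_levels: int) -> dict[str, float]:
    """16 GLSZM features (direction-free)."""
    n_vox = int(np.asarray(roi_mask, dtype=bool).sum())
    return glszm_features(glszm_matrix(levels, roi_mask, n_levels), n_vox)


def gldm(levels, roi_mask, n_levels: int, alpha: int = 0) -> dict[str, float]:
    """14 GLDM features (direction-free)."""
    return gldm_features(gldm_matrix(levels, roi_mask, n_levels, alpha=alpha))


def ngtdm(levels, roi_mask, n_levels: int) -> dict[str, float]:
    """5 NGTDM features."""
    n_i, s_i = ngtdm_table(levels, roi_mask, n_levels)
    return ngtdm_features(n_i, s_i)
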