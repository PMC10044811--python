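"""Brute-force oracles for the texture and first-order features.

Everything here is written as plain nested loops straight from the feature
definitions: pairs, runs, zones, dependencies and neighborhoods are
enumerated voxel by voxel, and the feature formulas are evaluated with
scalar arithmetic.  No code is shared with the package's vectorized
engine; these functions are only usable on tiny fixtures.
"""

from __future__ import annotations

import math

import numpy as np

EPS = np.spacing(1.0)

OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, x, y, z):
    return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]


def _roi_voxels(mask):
    return [tuple(v) for v in np.argwhere(mask)]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_oracle(lvl, mask, n_levels):
    per_direction = []
    for off in OFFSETS_13:
        counts = np.zeros((n_levels, n_levels))
        for (x, y, z) in _roi_voxels(mask):
            nx, ny, nz = x + off[0], y + off[1], z + off[2]
            if _in(mask.shape, nx, ny, nz) and mask[nx, ny, nz]:
                a, b = lvl[x, y, z] - 1, lvl[nx, ny, nz] - 1
                counts[a, b] += 1
                counts[b, a] += 1
        if counts.sum() > 0:
            per_direction.append(_glcm_formulas(counts / counts.sum()))
    keys = per_direction[0].keys()
    return {k: float(np.mean([d[k] for d in per_direction])) for k in keys}


def _glcm_formulas(p):
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    varx = sum(px[i] * ((i + 1) - mux) ** 2 for i in range(ng))
    vary = sum(py[j] * ((j + 1) - muy) ** 2 for j in range(ng))
    psum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pdiff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]

    out = {}
    out["Autocorrelation"] = sum(
        p[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
    )
    out["JointAverage"] = mux
    for power, name in ((4, "ClusterProminence"), (3, "ClusterShade"), (2, "ClusterTendency")):
        out[name] = sum(
            p[i][j] * ((i + 1) + (j + 1) - mux - muy) ** power
            for i in range(ng)
            for j in range(ng)
        )
    out["Contrast"] = sum(
        p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
    )
    if varx * vary == 0:
        out["Correlation"] = 1.0
    else:
        out["Correlation"] = (
            sum(p[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng))
            - mux * muy
        ) / math.sqrt(varx * vary)
    da = sum(k * v for k, v in pdiff.items())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(v * math.log2(v + EPS) for v in pdiff.values())
    out["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in pdiff.items())
    out["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(
        p[i][j] * math.log2(p[i][j] + EPS) for i in range(ng) for j in range(ng)
    )
    out["JointEntropy"] = hxy
    hx = -sum(px[i] * math.log2(px[i] + EPS) for i in range(ng))
    hy = -sum(py[j] * math.log2(py[j] + EPS) for j in range(ng))
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j] + EPS) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + EPS)
        for i in range(ng)
        for j in range(ng)
    )
    out["Imc1"] = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    out["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["Idm"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["Idmn"] = sum(
        p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    out["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    out["Idn"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["InverseVariance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    out["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    out["SumAverage"] = sum(k * v for k, v in psum.items())
    out["SumEntropy"] = -sum(v * math.log2(v + EPS) for v in psum.values())
    out["SumSquares"] = sum(
        p[i][j] * ((i + 1) - mux) ** 2 for i in range(ng) for j in range(ng)
    )
    nz = [i for i in range(ng) if px[i] > 0]
    if len(nz) <= 1:
        out["MCC"] = 1.0
    else:
        q = np.zeros((len(nz), len(nz)))
        for a, i in enumerate(nz):
            for b, j in enumerate(nz):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k]) for k in nz if py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        out["MCC"] = math.sqrt(max(0.0, eig[-2]))
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_in_direction(lvl, mask, off):
    """Enumerate (gray level, run length) of maximal runs along one offset."""
    runs = []
    shape = mask.shape
    for (x, y, z) in _roi_voxels(mask):
        px_, py_, pz_ = x - off[0], y - off[1], z - off[2]
        starts_run = not (
            _in(shape, px_, py_, pz_)
            and mask[px_, py_, pz_]
            and lvl[px_, py_, pz_] == lvl[x, y, z]
        )
        if not starts_run:
            continue
        length = 1
        cx, cy, cz = x + off[0], y + off[1], z + off[2]
        while _in(shape, cx, cy, cz) and mask[cx, cy, cz] and lvl[cx, cy, cz] == lvl[x, y, z]:
            length += 1
            cx, cy, cz = cx + off[0], cy + off[1], cz + off[2]
        runs.append((int(lvl[x, y, z]), length))
    return runs


def glrlm_oracle(lvl, mask, n_levels):
    n_vox = int(mask.sum())
    per_direction = []
    for off in OFFSETS_13:
        runs = _runs_in_direction(lvl, mask, off)
        max_len = max(r for _, r in runs)
        mat = np.zeros((n_levels, max_len))
        for g, r in runs:
            mat[g - 1, r - 1] += 1
        per_direction.append(_rl_formulas(mat, n_vox, zone=False))
    keys = per_direction[0].keys()
    return {k: float(np.mean([d[k] for d in per_direction])) for k in keys}


def _rl_formulas(mat, n_vox, zone):
    total = mat.sum()
    ng, nl = mat.shape
    names = {
        True: ("SmallArea", "LargeArea", "SizeZone", "Zone", "ZonePercentage",
               "ZoneVariance", "ZoneEntropy", "Zone"),
        False: ("ShortRun", "LongRun", "RunLength", "Run", "RunPercentage",
                "RunVariance", "RunEntropy", "Run"),
    }[zone]
    short, long_, rlnu_prefix, _, pct_name, var_name, ent_name, _ = names
    out = {}
    out[f"{short}Emphasis"] = sum(
        mat[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / total
    out[f"{long_}Emphasis"] = sum(
        mat[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / total
    out["GrayLevelNonUniformity"] = sum(
        sum(mat[i][j] for j in range(nl)) ** 2 for i in range(ng)
    ) / total
    out["GrayLevelNonUniformityNormalized"] = sum(
        sum(mat[i][j] for j in range(nl)) ** 2 for i in range(ng)
    ) / total**2
    out[f"{rlnu_prefix}NonUniformity"] = sum(
        sum(mat[i][j] for i in range(ng)) ** 2 for j in range(nl)
    ) / total
    out[f"{rlnu_prefix}NonUniformityNormalized"] = sum(
        sum(mat[i][j] for i in range(ng)) ** 2 for j in range(nl)
    ) / total**2
    out[pct_name] = total / n_vox
    mu_i = sum(mat[i][j] / total * (i + 1) for i in range(ng) for j in range(nl))
    mu_j = sum(mat[i][j] / total * (j + 1) for i in range(ng) for j in range(nl))
    out["GrayLevelVariance"] = sum(
        mat[i][j] / total * ((i + 1) - mu_i) ** 2 for i in range(ng) for j in range(nl)
    )
    out[var_name] = sum(
        mat[i][j] / total * ((j + 1) - mu_j) ** 2 for i in range(ng) for j in range(nl)
    )
    out[ent_name] = -sum(
        mat[i][j] / total * math.log2(mat[i][j] / total + EPS)
        for i in range(ng)
        for j in range(nl)
    )
    lo = "LowGrayLevelZoneEmphasis" if zone else "LowGrayLevelRunEmphasis"
    hi = "HighGrayLevelZoneEmphasis" if zone else "HighGrayLevelRunEmphasis"
    out[lo] = sum(
        mat[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / total
    out[hi] = sum(
        mat[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / total
    out[f"{short}LowGrayLevelEmphasis"] = sum(
        mat[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nl)
    ) / total
    out[f"{short}HighGrayLevelEmphasis"] = sum(
        mat[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / total
    out[f"{long_}LowGrayLevelEmphasis"] = sum(
        mat[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / total
    out[f"{long_}HighGrayLevelEmphasis"] = sum(
        mat[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / total
    return out


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def _zones(lvl, mask):
    """Flood-fill 26-connected equal-level zones."""
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in _roi_voxels(mask):
        if seen[start]:
            continue
        g = lvl[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for off in OFFSETS_26:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if (
                    _in(mask.shape, *w)
                    and mask[w]
                    and not seen[w]
                    and lvl[w] == g
                ):
                    seen[w] = True
                    stack.append(w)
        zones.append((int(g), size))
    return zones


def glszm_oracle(lvl, mask, n_levels):
    zones = _zones(lvl, mask)
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return _rl_formulas(mat, int(mask.sum()), zone=True)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_oracle(lvl, mask, n_levels, alpha=0):
    deps = []
    for (x, y, z) in _roi_voxels(mask):
        d = 0
        for off in OFFSETS_26:
            w = (x + off[0], y + off[1], z + off[2])
            if _in(mask.shape, *w) and mask[w] and abs(int(lvl[w]) - int(lvl[x, y, z])) <= alpha:
                d += 1
        deps.append((int(lvl[x, y, z]), d))
    max_dep = max(d for _, d in deps)
    mat = np.zeros((n_levels, max_dep + 1))
    for g, d in deps:
        mat[g - 1, d] += 1
    total = mat.sum()
    ng, nd = mat.shape
    out = {}
    # dependence size = neighbor count + 1 (center voxel included)
    out["SmallDependenceEmphasis"] = sum(
        mat[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / total
    out["LargeDependenceEmphasis"] = sum(
        mat[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / total
    out["GrayLevelNonUniformity"] = sum(
        sum(mat[i][j] for j in range(nd)) ** 2 for i in range(ng)
    ) / total
    out["DependenceNonUniformity"] = sum(
        sum(mat[i][j] for i in range(ng)) ** 2 for j in range(nd)
    ) / total
    out["DependenceNonUniformityNormalized"] = sum(
        sum(mat[i][j] for i in range(ng)) ** 2 for j in range(nd)
    ) / total**2
    mu_i = sum(mat[i][j] / total * (i + 1) for i in range(ng) for j in range(nd))
    mu_j = sum(mat[i][j] / total * (j + 1) for i in range(ng) for j in range(nd))
    out["GrayLevelVariance"] = sum(
        mat[i][j] / total * ((i + 1) - mu_i) ** 2 for i in range(ng) for j in range(nd)
    )
    out["DependenceVariance"] = sum(
        mat[i][j] / total * ((j + 1) - mu_j) ** 2 for i in range(ng) for j in range(nd)
    )
    out["DependenceEntropy"] = -sum(
        mat[i][j] / total * math.log2(mat[i][j] / total + EPS)
        for i in range(ng)
        for j in range(nd)
    )
    out["LowGrayLevelEmphasis"] = sum(
        mat[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / total
    out["HighGrayLevelEmphasis"] = sum(
        mat[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / total
    out["SmallDependenceLowGrayLevelEmphasis"] = sum(
        mat[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nd)
    ) / total
    out["SmallDependenceHighGrayLevelEmphasis"] = sum(
        mat[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / total
    out["LargeDependenceLowGrayLevelEmphasis"] = sum(
        mat[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / total
    out["LargeDependenceHighGrayLevelEmphasis"] = sum(
        mat[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / total
    return out


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_oracle(lvl, mask, n_levels):
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for (x, y, z) in _roi_voxels(mask):
        nb = []
        for off in OFFSETS_26:
            w = (x + off[0], y + off[1], z + off[2])
            if _in(mask.shape, *w) and mask[w]:
                nb.append(int(lvl[w]))
        if not nb:
            continue
        g = int(lvl[x, y, z])
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(nb) / len(nb))
    n_total = n_i.sum()
    p_i = n_i / n_total
    levels = list(range(1, n_levels + 1))
    nz = [i for i in range(n_levels) if p_i[i] > 0]
    ngp = len(nz)

    coarse_den = sum(p_i[i] * s_i[i] for i in range(n_levels))
    coarseness = 1e6 if coarse_den == 0 else 1.0 / coarse_den
    if ngp == 1:
        contrast = 0.0
        complexity = 0.0
        strength = 0.0
    else:
        contrast = (
            sum(p_i[i] * p_i[j] * (levels[i] - levels[j]) ** 2 for i in nz for j in nz)
            / (ngp * (ngp - 1))
        ) * (s_i.sum() / n_total)
        complexity = (
            sum(
                abs(levels[i] - levels[j])
                * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                / (p_i[i] + p_i[j])
                for i in nz
                for j in nz
            )
            / n_total
        )
        strength = (
            0.0
            if s_i.sum() == 0
            else sum(
                (p_i[i] + p_i[j]) * (levels[i] - levels[j]) ** 2 for i in nz for j in nz
            )
            / s_i.sum()
        )
    busy_den = sum(
        abs(levels[i] * p_i[i] - levels[j] * p_i[j]) for i in nz for j in nz
    )
    busyness = 0.0 if busy_den == 0 else coarse_den / busy_den
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
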