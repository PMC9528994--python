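"""Gray-level texture matrices and their features.

Five families: GLCM (22), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5).
Matrices are built in 3D with 26-connectivity / Chebyshev distance 1.
GLCM and GLRLM are computed per angle (13 unique 3D directions) and the
feature values averaged over angles; GLSZM/GLDM/NGTDM are single-matrix.

Gray levels i, j entering the formulas are the actual discretised level
values present in the ROI (not re-indexed), matching the reference
implementation.  Zero rows/columns are omitted from normalisation.
"""

from __future__ import annotations

import functools
import logging

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

logger = logging.getLogger("fwlomics")

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")

# 13 unique direction vectors: first non-zero component positive.
ANGLES = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(ANGLES) == 13

_EPS = np.spacing(1.0)


def _pair_slices(shape, off):
    """Slices (sl_a, sl_b) such that arr[sl_b] is arr[sl_a] shifted by off."""
    sl_a, sl_b = [], []
    for n, d in zip(shape, off):
        if d == 0:
            sl_a.append(slice(None)), sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, n - d)), sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n)), sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def glcm_matrices(levels: np.ndarray, mask: np.ndarray):
    """Symmetric co-occurrence count matrices, one per angle.

    Returns (stack of shape (13, Ng, Ng), present level values).
    """
    vals = np.unique(levels[mask])
    idx = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    idx[vals] = np.arange(len(vals))
    ng = len(vals)
    out = np.zeros((len(ANGLES), ng, ng), dtype=np.float64)
    for k, off in enumerate(ANGLES):
        sa, sb = _pair_slices(levels.shape, off)
        valid = mask[sa] & mask[sb]
        a = idx[levels[sa][valid]]
        b = idx[levels[sb][valid]]
        m = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        out[k] = m + m.T
    return out, vals.astype(np.float64)


@functools.lru_cache(maxsize=8)
def _run_traversals(shape: tuple[int, int, int]):
    """Per-angle voxel orderings for run-length extraction.

    For each direction d the grid decomposes into parallel lines; voxels on
    one line share the invariant key (pos - t*d).  Returns, per angle, the
    flat voxel order sorted by (line key, t) and a boolean marking where a
    new line starts.
    """
    coords = np.indices(shape).reshape(3, -1)
    res = []
    for off in ANGLES:
        d = np.array(off).reshape(3, 1)
        axis = int(np.nonzero(off)[0][0])
        t = coords[axis] * off[axis]
        key = coords - t * d
        order = np.lexsort((t, key[2], key[1], key[0]))
        k_sorted = key[:, order]
        newline = np.ones(order.size, dtype=bool)
        newline[1:] = (np.diff(k_sorted, axis=1) != 0).any(axis=0)
        res.append((order, newline))
    return res


def glrlm_matrices(levels: np.ndarray, mask: np.ndarray):
    """Run-length count matrices P(level, run length), one per angle."""
    vals = np.unique(levels[mask])
    idx = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    idx[vals] = np.arange(len(vals))
    ng = len(vals)
    max_run = max(levels.shape) if len(levels.shape) else 1
    flat = levels.ravel()
    out = np.zeros((len(ANGLES), ng, max_run), dtype=np.float64)
    for k, (order, newline) in enumerate(_run_traversals(levels.shape)):
        seq = flat[order]
        brk = newline.copy()
        brk[1:] |= seq[1:] != seq[:-1]
        starts = np.nonzero(brk)[0]
        lengths = np.diff(np.append(starts, seq.size))
        run_levels = seq[starts]
        keep = run_levels > 0
        li = idx[run_levels[keep]]
        lj = lengths[keep] - 1
        np.add.at(out[k], (li, lj), 1.0)
    # trim trailing all-zero run lengths (keep at least one column)
    used = max(int(np.nonzero(out.sum(axis=(0, 1)))[0].max()) + 1, 1)
    return out[:, :, :used], vals.astype(np.float64)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray):
    """Zone-size count matrix P(level, zone size), 26-connected zones."""
    vals = np.unique(levels[mask])
    size_counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for g in vals:
        lab, n = ndimage.label(levels == g, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            size_counts[(g, int(s))] = size_counts.get((g, int(s)), 0) + 1
            max_size = max(max_size, int(s))
    ng = len(vals)
    out = np.zeros((ng, max_size), dtype=np.float64)
    vidx = {int(g): i for i, g in enumerate(vals)}
    for (g, s), c in size_counts.items():
        out[vidx[int(g)], s - 1] = c
    return out, vals.astype(np.float64)


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, alpha: int = 0):
    """Dependence matrix P(level, dependence size).

    A 26-neighbour is dependent when |level difference| <= alpha; the
    dependence size counts the centre voxel plus its dependent neighbours.
    """
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in ANGLES:
        sa, sb = _pair_slices(levels.shape, off)
        valid = mask[sa] & mask[sb]
        close = np.abs(levels[sa] - levels[sb]) <= alpha
        hit = valid & close
        dep[sa] += hit
        dep[sb] += hit
    dep = dep + 1  # centre voxel counts
    vals = np.unique(levels[mask])
    idx = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    idx[vals] = np.arange(len(vals))
    ng = len(vals)
    nd = int(dep[mask].max())
    out = np.zeros((ng, nd), dtype=np.float64)
    np.add.at(out, (idx[levels[mask]], dep[mask] - 1), 1.0)
    return out, vals.astype(np.float64)


def ngtdm_table(levels: np.ndarray, mask: np.ndarray):
    """Per-level (n_i, p_i, s_i) for the neighbourhood gray-tone
    difference features; s_i sums |level - mean of 26-neighbours|."""
    kern = np.ones((3, 3, 3))
    kern[1, 1, 1] = 0
    m = mask.astype(np.float64)
    nsum = ndimage.correlate(levels * m, kern, mode="constant", cval=0.0)
    ncnt = ndimage.correlate(m, kern, mode="constant", cval=0.0)
    valid = mask & (ncnt > 0)
    vals = np.unique(levels[mask])
    ng = len(vals)
    idx = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    idx[vals] = np.arange(ng)
    diff = np.zeros(levels.shape)
    diff[valid] = np.abs(levels[valid] - nsum[valid] / ncnt[valid])
    n_i = np.bincount(idx[levels[valid]], minlength=ng).astype(np.float64)
    s_i = np.bincount(idx[levels[valid]], weights=diff[valid], minlength=ng)
    nvp = n_i.sum()
    p_i = n_i / nvp if nvp > 0 else n_i
    return n_i, p_i, s_i, vals.astype(np.float64)


# ---------------------------------------------------------------------------
# Features from matrices
# ---------------------------------------------------------------------------

def glcm_features_from_matrix(counts: np.ndarray, vals: np.ndarray) -> dict[str, float]:
    """22 GLCM features from one angle's symmetric count matrix."""
    total = counts.sum()
    if total == 0:
        return {n: 0.0 for n in GLCM_NAMES}
    p = counts / total
    ng = len(vals)
    i = vals.reshape(-1, 1)
    j = vals.reshape(1, -1)
    px = p.sum(axis=1)
    mu_x = float((vals * px).sum())
    sig_x = float(np.sqrt(((vals - mu_x) ** 2 * px).sum()))
    dif = np.abs(i - j)
    # p_{x+y} and p_{x-y} over realised sums/differences
    sums = (i + j).ravel()
    difs = dif.ravel()
    pr = p.ravel()
    us, inv_s = np.unique(sums, return_inverse=True)
    p_sum = np.bincount(inv_s, weights=pr)
    ud, inv_d = np.unique(difs, return_inverse=True)
    p_dif = np.bincount(inv_d, weights=pr)

    ent = lambda q: float(-(q[q > 0] * np.log2(q[q > 0])).sum())
    hxy = ent(pr)
    hx = ent(px)
    pxpy = px.reshape(-1, 1) * px.reshape(1, -1)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    max_h = max(hx, hx)  # symmetric matrix: HX == HY
    imc1 = (hxy - hxy1) / max_h if max_h > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    da = float((ud * p_dif).sum())
    corr_den = sig_x * sig_x
    autoc = float((p * i * j).sum())
    correlation = (autoc - mu_x * mu_x) / corr_den if corr_den > 0 else 1.0
    off_diag = dif > 0
    inv_var = float((p[off_diag] / (dif[off_diag] ** 2)).sum()) if off_diag.any() else 0.0

    return {
        "Autocorrelation": autoc,
        "JointAverage": mu_x,
        "ClusterProminence": float((p * (i + j - 2 * mu_x) ** 4).sum()),
        "ClusterShade": float((p * (i + j - 2 * mu_x) ** 3).sum()),
        "ClusterTendency": float((p * (i + j - 2 * mu_x) ** 2).sum()),
        "Contrast": float((p * (i - j) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_dif),
        "DifferenceVariance": float(((ud - da) ** 2 * p_dif).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((i - j) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + dif)).sum()),
        "Idn": float((p / (1.0 + dif / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float((p * (i - mu_x) ** 2).sum()),
    }


GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
)


def glrlm_features_from_matrix(P: np.ndarray, vals: np.ndarray, n_voxels: int) -> dict[str, float]:
    """16 run-length features from one angle's run count matrix."""
    nr = P.sum()
    if nr == 0:
        return {n: 0.0 for n in GLRLM_NAMES}
    i = vals.reshape(-1, 1)
    lengths = np.arange(1, P.shape[1] + 1, dtype=np.float64).reshape(1, -1)
    p = P / nr
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_l = float((p * lengths).sum())
    pn = p[p > 0]
    return {
        "ShortRunEmphasis": float((P / lengths**2).sum() / nr),
        "LongRunEmphasis": float((P * lengths**2).sum() / nr),
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "RunLengthNonUniformity": float((pl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (lengths - mu_l) ** 2).sum()),
        "RunEntropy": float(-(pn * np.log2(pn)).sum()),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * lengths**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / lengths**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * lengths**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * lengths**2).sum() / nr),
    }


GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def glszm_features_from_matrix(P: np.ndarray, vals: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = P.sum()
    if nz == 0:
        return {n: 0.0 for n in GLSZM_NAMES}
    i = vals.reshape(-1, 1)
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64).reshape(1, -1)
    p = P / nz
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    pn = p[p > 0]
    return {
        "SmallAreaEmphasis": float((P / s**2).sum() / nz),
        "LargeAreaEmphasis": float((P * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(pn * np.log2(pn)).sum()),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / nz),
    }


GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def gldm_features_from_matrix(P: np.ndarray, vals: np.ndarray) -> dict[str, float]:
    nz = P.sum()
    if nz == 0:
        return {n: 0.0 for n in GLDM_NAMES}
    i = vals.reshape(-1, 1)
    d = np.arange(1, P.shape[1] + 1, dtype=np.float64).reshape(1, -1)
    p = P / nz
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_d = float((p * d).sum())
    pn = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((P / d**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * d**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "DependenceNonUniformity": float((pd**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (d - mu_d) ** 2).sum()),
        "DependenceEntropy": float(-(pn * np.log2(pn)).sum()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * d**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / d**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * d**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * d**2).sum() / nz),
    }


GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_COARSENESS_CAP = 1e6


def ngtdm_features_from_table(n_i, p_i, s_i, vals) -> dict[str, float]:
    nvp = n_i.sum()
    act = p_i > 0
    ngp = int(act.sum())
    iv = vals
    denom = float((p_i * s_i).sum())
    coarseness = 1.0 / denom if denom > 0 else _COARSENESS_CAP
    if ngp <= 1:
        contrast = 0.0
        busyness = 0.0
        strength = 0.0
    else:
        pi_a, iv_a, si_a = p_i[act], iv[act], s_i[act]
        dmat = (iv_a.reshape(-1, 1) - iv_a.reshape(1, -1)) ** 2
        pp = pi_a.reshape(-1, 1) * pi_a.reshape(1, -1)
        contrast = (
            float((pp * dmat).sum()) / (ngp * (ngp - 1)) * float(s_i.sum()) / nvp
            if nvp > 0 else 0.0
        )
        bus_den = float(
            np.abs(iv_a.reshape(-1, 1) * pi_a.reshape(-1, 1)
                   - iv_a.reshape(1, -1) * pi_a.reshape(1, -1)).sum()
        )
        busyness = denom / bus_den if bus_den > 0 else 0.0
        s_sum = float(s_i.sum())
        strength = (
            float(((pi_a.reshape(-1, 1) + pi_a.reshape(1, -1)) * dmat).sum()) / s_sum
            if s_sum > 0 else 0.0
        )
    # Complexity is defined for all ngp >= 1 (zero when one level)
    if ngp <= 1 or nvp == 0:
        complexity = 0.0
    else:
        pi_a, iv_a, si_a = p_i[act], iv[act], s_i[act]
        absd = np.abs(iv_a.reshape(-1, 1) - iv_a.reshape(1, -1))
        num = (pi_a.reshape(-1, 1) * si_a.reshape(-1, 1)
               + pi_a.reshape(1, -1) * si_a.reshape(1, -1))
        den = pi_a.reshape(-1, 1) + pi_a.reshape(1, -1)
        complexity = float((absd * num / den).sum() / nvp)
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FAMILY_NAMES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def texture_features(d: DiscretizedROI, family: str) -> dict[str, float]:
    """Compute one family's features for a discretised ROI.

    GLCM/GLRLM: per-angle feature values averaged over the 13 angles
    (angles with an empty matrix are skipped, as in the reference
    implementation).  Single-voxel ROIs yield degenerate values from the
    corresponding 1x1 matrices.
    """
    levels, mask = d.levels, d.mask
    if d.n_voxels == 1:
        logger.debug("single-voxel ROI: degenerate %s features", family)
    if family == "glcm":
        mats, vals = glcm_matrices(levels, mask)
        per = [glcm_features_from_matrix(m, vals) for m in mats if m.sum() > 0]
        if not per:
            per = [glcm_features_from_matrix(np.zeros((1, 1)), vals[:1])]
        return {k: float(np.mean([f[k] for f in per])) for k in GLCM_NAMES}
    if family == "glrlm":
        mats, vals = glrlm_matrices(levels, mask)
        per = [glrlm_features_from_matrix(m, vals, d.n_voxels) for m in mats]
        return {k: float(np.mean([f[k] for f in per])) for k in GLRLM_NAMES}
    if family == "glszm":
        P, vals = glszm_matrix(levels, mask)
        return glszm_features_from_matrix(P, vals, d.n_voxels)
    if family == "gldm":
        P, vals = gldm_matrix(levels, mask)
        return gldm_features_from_matrix(P, vals)
    if family == "ngtdm":
        return ngtdm_features_from_table(*ngtdm_table(levels, mask))
    raise ValueError(f"unknown texture family {family!r}")
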