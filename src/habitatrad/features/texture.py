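"""Gray-level texture matrices and their statistics.

All four families operate on a fixed-bin-width discretization of the region
intensities (levels 1..Ng).  Directional families (GLCM, GLRLM) use the 13
unique 3D direction vectors and average each statistic over directions, the
common IBSI aggregation.  GLSZM zones and NGTDM neighbourhoods use
26-connectivity.

Degenerate regions (fewer than 2 voxels, or no valid voxel pairs) yield NaN
for every statistic of the affected family; a constant region yields the
analytic single-level values (e.g. GLCM contrast 0).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "GLCM_NAMES", "GLCM_REDUCED_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "NGTDM_NAMES",
    "discretize", "glcm_features", "glrlm_features", "glszm_features", "ngtdm_features",
]

_EPS = np.finfo(float).eps

# 13 unique direction vectors (half of the 26-neighbourhood)
DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]
#: reduced set used for the supplementary distance-2 block: the five
#: normalized/information-theoretic statistics are omitted
GLCM_REDUCED_NAMES = [n for n in GLCM_NAMES if n not in ("Imc1", "Imc2", "Idmn", "Idn", "MCC")]

GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def discretize(arr: np.ndarray, mask: np.ndarray, bin_width: float = 0.25) -> tuple[np.ndarray, int]:
    """Fixed-bin-width discretization to levels 1..Ng inside the mask
    (0 outside).  Returns the level grid and Ng."""
    disc = np.zeros(arr.shape, dtype=np.int32)
    vals = arr[mask]
    if vals.size == 0:
        return disc, 0
    lo = vals.min()
    levels = np.floor((vals - lo) / bin_width).astype(np.int32) + 1
    ng = int(levels.max())
    disc[mask] = levels
    return disc, ng


def _shift_slices(shape, off):
    """Index slices (src, dst) pairing voxel v with voxel v+off."""
    src, dst = [], []
    for dim, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, dim - o))
            dst.append(slice(o, dim))
        else:
            src.append(slice(-o, dim))
            dst.append(slice(0, dim + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrices(disc: np.ndarray, ng: int, distance: int) -> np.ndarray:
    mats = []
    for d in DIRECTIONS:
        off = tuple(distance * o for o in d)
        src, dst = _shift_slices(disc.shape, off)
        a = disc[src].ravel()
        b = disc[dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid] - 1) * ng + (b[valid] - 1)
        m = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(float)
        mats.append(m + m.T)  # symmetric
    return np.stack(mats) if mats else np.empty((0, ng, ng))


def glcm_features(
    disc: np.ndarray, ng: int, distance: int = 1, names: list[str] | None = None
) -> dict[str, float]:
    names = names if names is not None else GLCM_NAMES
    if ng < 1:
        return {n: np.nan for n in names}
    mats = _glcm_matrices(disc, ng, distance)
    if len(mats) == 0:
        return {n: np.nan for n in names}
    p = mats / mats.sum(axis=(1, 2), keepdims=True)  # (A, Ng, Ng)
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[None, :, None]
    jj = i[None, None, :]
    px = p.sum(axis=2)  # (A, Ng)
    py = p.sum(axis=1)
    mux = (px * i).sum(axis=1)
    muy = (py * i).sum(axis=1)
    sigx = np.sqrt((px * (i - mux[:, None]) ** 2).sum(axis=1))
    sigy = np.sqrt((py * (i - muy[:, None]) ** 2).sum(axis=1))

    absdiff = np.abs(ii - jj)
    sumij = ii + jj
    # p_{x-y}(k), k = 0..Ng-1 ; p_{x+y}(k), k = 2..2Ng
    pxmy = np.stack([(p * (absdiff == k)).sum(axis=(1, 2)) for k in range(ng)], axis=1)
    pxpy = np.stack([(p * (sumij == k)).sum(axis=(1, 2)) for k in range(2, 2 * ng + 1)], axis=1)
    kd = np.arange(ng, dtype=float)
    ks = np.arange(2, 2 * ng + 1, dtype=float)

    da = (pxmy * kd).sum(axis=1)
    feats: dict[str, np.ndarray] = {}
    feats["Autocorrelation"] = (p * ii * jj).sum(axis=(1, 2))
    feats["JointAverage"] = mux
    for power, nm in ((4, "ClusterProminence"), (3, "ClusterShade"), (2, "ClusterTendency")):
        feats[nm] = (p * (sumij - mux[:, None, None] - muy[:, None, None]) ** power).sum(axis=(1, 2))
    feats["Contrast"] = (p * (ii - jj) ** 2).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = ((p * ii * jj).sum(axis=(1, 2)) - mux * muy) / (sigx * sigy)
    feats["Correlation"] = np.where(sigx * sigy > 0, corr, 1.0)
    feats["DifferenceAverage"] = da
    feats["DifferenceEntropy"] = -(pxmy * np.log2(pxmy + _EPS)).sum(axis=1)
    feats["DifferenceVariance"] = (pxmy * (kd - da[:, None]) ** 2).sum(axis=1)
    feats["JointEnergy"] = (p**2).sum(axis=(1, 2))
    hxy = -(p * np.log2(p + _EPS)).sum(axis=(1, 2))
    feats["JointEntropy"] = hxy
    pxy = px[:, :, None] * py[:, None, :]
    hxy1 = -(p * np.log2(pxy + _EPS)).sum(axis=(1, 2))
    hxy2 = -(pxy * np.log2(pxy + _EPS)).sum(axis=(1, 2))
    hx = -(px * np.log2(px + _EPS)).sum(axis=1)
    hy = -(py * np.log2(py + _EPS)).sum(axis=1)
    den = np.maximum(hx, hy)
    feats["Imc1"] = np.where(den > 0, (hxy - hxy1) / np.where(den > 0, den, 1.0), 0.0)
    feats["Imc2"] = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))
    feats["Idm"] = (p / (1.0 + (ii - jj) ** 2)).sum(axis=(1, 2))
    feats["Idmn"] = (p / (1.0 + ((ii - jj) / ng) ** 2)).sum(axis=(1, 2))
    feats["Id"] = (p / (1.0 + absdiff)).sum(axis=(1, 2))
    feats["Idn"] = (p / (1.0 + absdiff / ng)).sum(axis=(1, 2))
    offdiag = absdiff > 0
    feats["InverseVariance"] = np.where(
        offdiag.any(), (np.where(offdiag, p, 0.0) / np.where(offdiag, (ii - jj) ** 2, 1.0)).sum(axis=(1, 2)), 0.0
    )
    feats["MaximumProbability"] = p.max(axis=(1, 2))
    feats["SumAverage"] = (pxpy * ks).sum(axis=1)
    feats["SumEntropy"] = -(pxpy * np.log2(pxpy + _EPS)).sum(axis=1)
    feats["SumSquares"] = (p * (ii - mux[:, None, None]) ** 2).sum(axis=(1, 2))
    if "MCC" in names:
        mccs = []
        for a in range(p.shape[0]):
            if ng == 1:
                mccs.append(1.0)
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.einsum("ik,jk->ij", p[a], p[a] / np.maximum(py[a][None, :], _EPS))
                q = q / np.maximum(px[a][:, None], _EPS)
            ev = np.sort(np.real(np.linalg.eigvals(q)))
            mccs.append(float(np.sqrt(max(ev[-2], 0.0))) if len(ev) > 1 else 1.0)
        feats["MCC"] = np.asarray(mccs)
    return {n: float(np.mean(feats[n])) for n in names}


# ---------------------------------------------------------------------------
# GLRLM


def _run_matrix(disc: np.ndarray, ng: int, direction) -> np.ndarray:
    """Run-length counts N(g, l) along one direction via vectorized
    run-length propagation."""
    src, dst = _shift_slices(disc.shape, direction)
    eq = np.zeros(disc.shape, dtype=bool)
    eq[src] = (disc[src] == disc[dst]) & (disc[dst] > 0)
    eq &= disc > 0  # eq[v]: successor v+d continues the run
    # run length seen forward from each voxel
    length = (disc > 0).astype(np.int32)
    step = eq.copy()
    shift_len = np.zeros_like(length)
    maxlen = max(disc.shape)
    for _ in range(maxlen):
        if not step.any():
            break
        shift_len[...] = 0
        shift_len[src] = length[dst]
        new_length = np.where(step, 1 + shift_len, length)
        if np.array_equal(new_length, length):
            break
        length = new_length
    # run starts: voxels with no same-valued predecessor
    pred = np.zeros(disc.shape, dtype=bool)
    pred[dst] = (disc[dst] == disc[src]) & (disc[src] > 0)
    starts = (disc > 0) & ~pred
    g = disc[starts] - 1
    l = length[starts] - 1
    lmax = int(l.max()) + 1 if l.size else 1
    mat = np.zeros((ng, lmax))
    np.add.at(mat, (g, l), 1.0)
    return mat


def _rlm_stats(mat: np.ndarray) -> dict[str, float]:
    nr = mat.sum()
    nvox = (mat * np.arange(1, mat.shape[1] + 1)[None, :]).sum()
    g = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    p = mat / nr
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mug = (p * g).sum()
    mul = (p * l).sum()
    return {
        "ShortRunEmphasis": float((p / l**2).sum()),
        "LongRunEmphasis": float((p * l**2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "RunLengthNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl**2).sum()),
        "RunPercentage": float(nr / nvox),
        "GrayLevelVariance": float((p * (g - mug) ** 2).sum()),
        "RunVariance": float((p * (l - mul) ** 2).sum()),
        "RunEntropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "LowGrayLevelRunEmphasis": float((p / g**2).sum()),
        "HighGrayLevelRunEmphasis": float((p * g**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (g**2 * l**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * g**2 / l**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * l**2 / g**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * g**2 * l**2).sum()),
    }


def glrlm_features(disc: np.ndarray, ng: int) -> dict[str, float]:
    if ng < 1 or (disc > 0).sum() < 2:
        return {n: np.nan for n in GLRLM_NAMES}
    per_dir = [_rlm_stats(_run_matrix(disc, ng, d)) for d in DIRECTIONS]
    return {n: float(np.mean([s[n] for s in per_dir])) for n in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(disc: np.ndarray, ng: int) -> dict[str, float]:
    if ng < 1 or (disc > 0).sum() < 2:
        return {n: np.nan for n in GLSZM_NAMES}
    zones: list[tuple[int, int]] = []  # (level, size)
    for level in range(1, ng + 1):
        binm = disc == level
        if not binm.any():
            continue
        lab, nz = ndimage.label(binm, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    levels = np.array([z[0] for z in zones])
    sizes = np.array([z[1] for z in zones])
    smax = int(sizes.max())
    mat = np.zeros((ng, smax))
    np.add.at(mat, (levels - 1, sizes - 1), 1.0)

    nz = mat.sum()
    nvox = float((disc > 0).sum())
    g = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, smax + 1, dtype=float)[None, :]
    p = mat / nz
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mug = (p * g).sum()
    mus = (p * s).sum()
    return {
        "SmallAreaEmphasis": float((p / s**2).sum()),
        "LargeAreaEmphasis": float((p * s**2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "SizeZoneNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum()),
        "ZonePercentage": float(nz / nvox),
        "GrayLevelVariance": float((p * (g - mug) ** 2).sum()),
        "ZoneVariance": float((p * (s - mus) ** 2).sum()),
        "ZoneEntropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "LowGrayLevelZoneEmphasis": float((p / g**2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * g**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (g**2 * s**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * g**2 / s**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * s**2 / g**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * s**2 * g**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(disc: np.ndarray, ng: int) -> dict[str, float]:
    if ng < 1 or (disc > 0).sum() < 2:
        return {n: np.nan for n in NGTDM_NAMES}
    valid = disc > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.correlate(disc.astype(float) * valid, kernel, mode="constant")
    nb_cnt = ndimage.correlate(valid.astype(float), kernel, mode="constant")
    has_nb = valid & (nb_cnt > 0)
    avg = np.zeros_like(nb_sum)
    avg[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]

    levels = disc[has_nb]
    diffs = np.abs(levels - avg[has_nb])
    nvox = float(has_nb.sum())
    n_g = np.bincount(levels - 1, minlength=ng).astype(float)
    s_g = np.bincount(levels - 1, weights=diffs, minlength=ng)
    p_g = n_g / nvox

    present = p_g > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=float)
    ps, iv, sv = p_g[present], i[present], s_g[present]

    denom_coarse = float((ps * sv).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6
    if ngp > 1:
        contrast = float(
            (ps[:, None] * ps[None, :] * (iv[:, None] - iv[None, :]) ** 2).sum()
            / (ngp * (ngp - 1))
        ) * float(sv.sum() / nvox)
    else:
        contrast = 0.0
    busy_den = float(np.abs(iv[:, None] * ps[:, None] - iv[None, :] * ps[None, :]).sum())
    busyness = float((ps * sv).sum()) / busy_den if busy_den > 0 else 0.0
    pij = ps[:, None] + ps[None, :]
    complexity = float(
        (np.abs(iv[:, None] - iv[None, :]) * (ps[:, None] * sv[:, None] + ps[None, :] * sv[None, :]) / pij).sum()
    ) / nvox
    s_sum = float(sv.sum())
    strength = float((pij * (iv[:, None] - iv[None, :]) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
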