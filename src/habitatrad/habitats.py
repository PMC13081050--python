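"""Intratumoral habitat mapping.

Each tumor is partitioned into ~100 spatially constrained superpixels (3D
SLIC restricted to the tumor mask).  A 19-statistic first-order feature
vector summarizes every superpixel.  Superpixel features pooled over the
training cohort are standardized and clustered with K-means for each
candidate K; the K maximizing the Calinski-Harabasz index becomes the
habitat count, and the training centroids are frozen as a template so the
same habitats (H1..HK, ordered by descending centroid mean intensity) can be
mapped in any case by nearest-centroid assignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import slic
from sklearn.cluster import KMeans

from .imaging import ImageVolume, RegionMask

__all__ = [
    "SUPERPIXEL_FEATURE_NAMES",
    "SuperpixelPartition",
    "HabitatTemplate",
    "partition_superpixels",
    "superpixel_feature_matrix",
    "calinski_harabasz",
    "fit_habitat_template",
    "apply_template",
]

#: The per-superpixel first-order statistics (19).  Entropy/uniformity use a
#: 32-bin histogram over the segment's intensity range.
SUPERPIXEL_FEATURE_NAMES = [
    "mean", "median", "minimum", "maximum", "range", "variance", "stddev",
    "skewness", "kurtosis", "energy", "rms", "entropy", "uniformity",
    "p10", "p25", "p75", "p90", "mad", "rmad",
]


@dataclass
class SuperpixelPartition:
    labels: np.ndarray  # int grid, 0 outside tumor, 1..n inside
    n_segments_target: int
    n_segments_actual: int
    compactness: float


@dataclass
class HabitatTemplate:
    K: int
    centroids: np.ndarray  # K x F, standardized space
    feature_means: np.ndarray
    feature_sds: np.ndarray
    ch_curve: dict[int, float]
    k_range: tuple[int, int]
    seed: int
    feature_names: list[str] = field(default_factory=lambda: list(SUPERPIXEL_FEATURE_NAMES))
    dropped_features: list[str] = field(default_factory=list)
    winsor_z: float = 3.0  # |z| clip applied before clustering and mapping

    def to_json(self, path: str) -> None:
        obj = {
            "K": self.K,
            "centroids": self.centroids.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "ch_curve": {str(k): v for k, v in self.ch_curve.items()},
            "k_range": list(self.k_range),
            "seed": self.seed,
            "feature_names": self.feature_names,
            "dropped_features": self.dropped_features,
            "winsor_z": self.winsor_z,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "HabitatTemplate":
        with open(path) as fh:
            o = json.load(fh)
        return cls(
            K=o["K"],
            centroids=np.asarray(o["centroids"]),
            feature_means=np.asarray(o["feature_means"]),
            feature_sds=np.asarray(o["feature_sds"]),
            ch_curve={int(k): v for k, v in o["ch_curve"].items()},
            k_range=tuple(o["k_range"]),
            seed=o["seed"],
            feature_names=o["feature_names"],
            dropped_features=o["dropped_features"],
            winsor_z=o.get("winsor_z", 3.0),
        )


def partition_superpixels(
    volume: ImageVolume,
    tumor: RegionMask,
    n_target: int = 100,
    compactness: float = 0.1,
) -> SuperpixelPartition:
    """Mask-constrained 3D SLIC over z-scored tumor intensities."""
    if tumor.voxel_count == 0:
        raise ValueError("tumor mask is empty")
    if not volume.same_grid(tumor):
        raise ValueError("volume and tumor mask must share one grid")
    nvox = tumor.voxel_count
    if nvox < 2:
        warnings.warn("tumor smaller than 2 voxels: single-segment partition")
        labels = tumor.labels.astype(np.int32)
        return SuperpixelPartition(labels, n_target, 1, compactness)

    inside = volume.voxels[tumor.labels]
    sd = inside.std()
    z = (volume.voxels - inside.mean()) / (sd if sd > 0 else 1.0)
    n_req = min(n_target, nvox)
    # run SLIC on the tumor bounding box only: cost scales with grid volume
    idx = np.argwhere(tumor.labels)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, tumor.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    seg_crop = slic(
        z[sl],
        n_segments=n_req,
        compactness=compactness,
        mask=tumor.labels[sl],
        spacing=tuple(volume.spacing),
        channel_axis=None,
        start_label=1,
        enforce_connectivity=True,
    )
    seg = np.zeros(tumor.shape, dtype=seg_crop.dtype)
    seg[sl] = seg_crop
    # relabel to contiguous 1..n (SLIC can skip labels under a mask)
    labels = np.zeros_like(seg, dtype=np.int32)
    for new, old in enumerate(np.unique(seg[seg > 0]), start=1):
        labels[seg == old] = new
    n_actual = int(labels.max())
    return SuperpixelPartition(labels, n_target, n_actual, compactness)


def _first_order_19(x: np.ndarray, bins: int = 32) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    d = x - mean
    var = float((d * d).mean())
    sd = np.sqrt(var)
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    if sd > 0:
        skew = float((d**3).mean() / sd**3)
        kurt = float((d**4).mean() / var**2)  # non-excess (Pearson)
    else:  # constant segment: degeneracy convention
        skew = 0.0
        kurt = 0.0
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=bins)
        p = hist[hist > 0] / x.size
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p**2).sum())
    else:
        entropy = 0.0
        uniformity = 1.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    return np.array([
        mean, med, x.min(), x.max(), x.max() - x.min(), var, sd, skew, kurt,
        float((x**2).sum()), float(np.sqrt((x**2).mean())), entropy, uniformity,
        p10, p25, p75, p90, float(np.abs(x - mean).mean()), rmad,
    ])


def superpixel_feature_matrix(volume: ImageVolume, part: SuperpixelPartition) -> np.ndarray:
    """One 19-statistic row per superpixel, in label order."""
    n = part.n_segments_actual
    out = np.empty((n, len(SUPERPIXEL_FEATURE_NAMES)))
    flat_labels = part.labels[part.labels > 0]
    flat_vals = volume.voxels[part.labels > 0]
    order = np.argsort(flat_labels, kind="stable")
    flat_labels = flat_labels[order]
    flat_vals = flat_vals[order]
    bounds = np.searchsorted(flat_labels, np.arange(1, n + 2))
    for i in range(n):
        out[i] = _first_order_19(flat_vals[bounds[i]:bounds[i + 1]])
    return out


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """CH index [B/(K-1)] / [W/(N-K)]: between- vs within-cluster dispersion.

    Returns +inf when the within-cluster dispersion is exactly zero.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    K, N = len(uniq), len(labels)
    if K <= 1:
        raise ValueError("need at least 2 clusters")
    if N <= K:
        raise ValueError("need more points than clusters")
    counts = np.bincount(inv)
    if np.any(counts == 0):
        raise ValueError("every cluster must be non-empty")
    grand = X.mean(axis=0)
    sums = np.zeros((K, X.shape[1]))
    np.add.at(sums, inv, X)
    cents = sums / counts[:, None]
    B = float((counts * ((cents - grand) ** 2).sum(axis=1)).sum())
    W = float(((X - cents[inv]) ** 2).sum())
    if W == 0:
        return float("inf")
    return (B / (K - 1)) / (W / (N - K))


def fit_habitat_template(
    matrices: list[np.ndarray],
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_init: int = 10,
    feature_names: list[str] | None = None,
    winsor_z: float = 3.0,
) -> HabitatTemplate:
    """Pool superpixel features across cases, standardize, and select K by CH.

    K-means (k-means++, ``n_init`` restarts, fixed seed) is fit for each K in
    ``k_range``; the template freezes the winning centroids (standardized
    space) with the pooled scaling statistics.  Habitat indices are ordered by
    descending centroid mean intensity so H1..HK are comparable across runs.

    Standardized features are winsorized at ``|z| = winsor_z`` before
    clustering: K-means and the CH index are sensitive to the rare
    boundary-straddling superpixels whose histogram statistics (skewness,
    uniformity) are many SDs out, which otherwise split off as spurious
    singleton clusters.  The clip is stored in the template and applied
    identically at mapping time.
    """
    names = list(feature_names) if feature_names is not None else list(SUPERPIXEL_FEATURE_NAMES)
    X = np.vstack(matrices)
    lo, hi = int(k_range[0]), int(k_range[1])
    if X.shape[0] < hi + 1:
        raise ValueError("need more pooled superpixels than max(k_range)")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"zero-variance features dropped from clustering: {dropped}")
    Z = (X[:, keep] - means[keep]) / sds[keep]
    Z = np.clip(Z, -winsor_z, winsor_z)

    ch_curve: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for K in range(lo, hi + 1):
        km = KMeans(n_clusters=K, n_init=n_init, random_state=seed).fit(Z)
        fits[K] = km
        ch_curve[K] = calinski_harabasz(Z, km.labels_)
    K_star = max(ch_curve, key=lambda k: (ch_curve[k], -k))
    cents = fits[K_star].cluster_centers_

    mean_col = names.index("mean") if "mean" in names else 0
    kept_names = [n for n, k in zip(names, keep) if k]
    if "mean" in kept_names:
        unscaled_mean = (
            cents[:, kept_names.index("mean")] * sds[keep][kept_names.index("mean")]
            + means[keep][kept_names.index("mean")]
        )
    else:  # fall back to first kept feature
        unscaled_mean = cents[:, 0]
    order = np.argsort(-unscaled_mean, kind="stable")
    del mean_col
    return HabitatTemplate(
        K=K_star,
        centroids=cents[order],
        feature_means=means,
        feature_sds=sds,
        ch_curve=ch_curve,
        k_range=(lo, hi),
        seed=seed,
        feature_names=names,
        dropped_features=dropped,
        winsor_z=winsor_z,
    )


def apply_template(
    template: HabitatTemplate,
    part: SuperpixelPartition,
    X: np.ndarray,
) -> list[RegionMask]:
    """Assign each superpixel to its nearest template centroid and return the
    K habitat masks (a partition of the tumor; empty habitats permitted)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(template.feature_names):
        raise ValueError("feature count does not match template")
    keep = template.feature_sds > 0
    Z = (X[:, keep] - template.feature_means[keep]) / template.feature_sds[keep]
    Z = np.clip(Z, -template.winsor_z, template.winsor_z)
    d2 = ((Z[:, None, :] - template.centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)  # 0..K-1
    masks = []
    for h in range(template.K):
        segs = np.flatnonzero(assign == h) + 1
        m = np.isin(part.labels, segs) & (part.labels > 0)
        masks.append(RegionMask(m, name=f"habitat{h + 1}"))
    return masks
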