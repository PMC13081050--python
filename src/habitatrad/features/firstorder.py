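"""First-order intensity statistics (18 per derived image)."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]


def firstorder_features(
    x: np.ndarray, voxel_volume: float = 1.0, bin_width: float = 0.25
) -> dict[str, float]:
    """The 18 first-order statistics on the region intensities ``x``.

    Entropy/uniformity use a fixed-bin-width discretization (IBSI style);
    skewness and kurtosis of a constant region are defined as 0, kurtosis is
    the non-excess (Pearson) form.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    p10, p25, med, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    rng = float(x.max() - x.min())
    if rng > 0:
        nbins = int(np.ceil(rng / bin_width)) or 1
        hist, _ = np.histogram(x, bins=nbins)
        p = hist[hist > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p**2).sum())
    else:
        entropy, uniformity = 0.0, 1.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": med,
        "InterquartileRange": p75 - p25,
        "Range": rng,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(sps.skew(x)) if sd > 0 else 0.0,
        "Kurtosis": float(sps.kurtosis(x, fisher=False)) if sd > 0 else 0.0,
        "Variance": var,
        "Uniformity": uniformity,
    }
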