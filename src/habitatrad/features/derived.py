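"""Derived (filtered) images for radiomic feature extraction.

The default panel computes features on 17 derived images: the original, the
eight sub-bands of a single-level undecimated Haar wavelet decomposition
(separable low/high-pass along each axis, same grid as the input), five
Laplacian-of-Gaussian responses (sigma 1..5 mm), and three pointwise
intensity transforms (square, square-root, logarithm, each sign-preserving
so they remain defined on z-scored intensities).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["DERIVED_IMAGE_NAMES", "derived_image", "wavelet_subband"]

_SQ2 = np.sqrt(2.0)
_LOW = np.array([1.0, 1.0]) / _SQ2   # Haar scaling filter
_HIGH = np.array([1.0, -1.0]) / _SQ2  # Haar wavelet filter

WAVELET_NAMES = [
    "wavelet-" + "".join(c) for c in
    ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
]
LOG_SIGMAS = (1.0, 2.0, 3.0, 4.0, 5.0)
LOG_NAMES = [f"log-sigma-{int(s)}mm" for s in LOG_SIGMAS]
TRANSFORM_NAMES = ["square", "squareroot", "logarithm"]

#: The 17 derived images of the default panel, in panel order.
DERIVED_IMAGE_NAMES = ["original"] + WAVELET_NAMES + LOG_NAMES + TRANSFORM_NAMES


def wavelet_subband(arr: np.ndarray, code: str) -> np.ndarray:
    """Undecimated single-level Haar sub-band; ``code`` like 'LHH' gives the
    filter (L=low, H=high) applied along axes 0, 1, 2 respectively."""
    out = np.asarray(arr, dtype=float)
    for axis, c in enumerate(code):
        w = _LOW if c == "L" else _HIGH
        out = ndimage.correlate1d(out, w, axis=axis, mode="nearest")
    return out


def derived_image(arr: np.ndarray, name: str, spacing: tuple[float, float, float]) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if name == "original":
        return arr
    if name.startswith("wavelet-"):
        return wavelet_subband(arr, name.split("-")[1])
    if name.startswith("log-sigma-"):
        sigma_mm = float(name.split("-")[2].replace("mm", ""))
        sig_vox = [sigma_mm / s for s in spacing]
        return ndimage.gaussian_laplace(arr, sigma=sig_vox)
    if name == "square":
        return np.sign(arr) * arr**2
    if name == "squareroot":
        return np.sign(arr) * np.sqrt(np.abs(arr))
    if name == "logarithm":
        return np.sign(arr) * np.log1p(np.abs(arr))
    raise ValueError(f"unknown derived image: {name}")
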