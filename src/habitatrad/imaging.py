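"""Volume/mask containers, NIfTI I/O, preprocessing contracts, and segmentation QC.

The pipeline operates on single enhanced-phase DCE-MRI volumes with binary
tumor masks delivered on the same voxel grid.  Preprocessing follows the
conventional radiomics recipe: resample everything to an isotropic grid
(trilinear for intensities, nearest-neighbour for labels), remove the
low-frequency coil/bias field with N4, and optionally z-score intensities
within the tumor-plus-ring support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "RegionMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "bias_correct",
    "normalize_intensity",
    "dice_coefficient",
]

DSC_QC_THRESHOLD = 0.85


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical geometry.

    voxels are indexed (i, j, k); ``spacing`` gives mm per axis in the same
    order; ``origin`` is the world position of voxel (0,0,0); ``direction``
    is the 3x3 axis-direction matrix (rows = world directions of the axes).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if min(self.voxels.shape) < 1:
            raise ValueError("each axis must have at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing values must be > 0")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("all intensities must be finite")
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_grid(self, other: "ImageVolume | RegionMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class RegionMask:
    """A binary label grid aligned to a paired :class:`ImageVolume`."""

    labels: np.ndarray
    name: str = "tumor"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError("labels must be a 3D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.labels = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing values must be > 0")
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())

    def same_grid(self, other: "ImageVolume | RegionMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel); geometry round-trips through the affine.


def _affine(spacing, origin, direction) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.asarray(direction) @ np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(aff):
    mat = aff[:3, :3]
    spacing = tuple(np.linalg.norm(mat, axis=0))
    direction = mat / np.array(spacing)[None, :]
    origin = tuple(aff[:3, 3])
    return spacing, origin, direction


def read_volume(path: str) -> ImageVolume:
    img = nib.load(path)
    spacing, origin, direction = _geometry_from_affine(img.affine)
    return ImageVolume(np.asarray(img.get_fdata(), dtype=np.float64), spacing, origin, direction)


def read_mask(path: str, name: str = "tumor") -> RegionMask:
    img = nib.load(path)
    spacing, origin, direction = _geometry_from_affine(img.affine)
    data = np.asarray(img.get_fdata())
    return RegionMask(data > 0.5, name=name, spacing=spacing, origin=origin, direction=direction)


def write_volume(vol: ImageVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(vol.voxels, _affine(vol.spacing, vol.origin, vol.direction)), path)


def write_mask(mask: RegionMask, path: str) -> None:
    nib.save(
        nib.Nifti1Image(mask.labels.astype(np.uint8), _affine(mask.spacing, mask.origin, mask.direction)),
        path,
    )


# ---------------------------------------------------------------------------
# SimpleITK bridge — sitk arrays are (z, y, x), ours (i, j, k) = (x, y, z).


def _to_sitk(arr: np.ndarray, spacing, origin, direction) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(origin))
    img.SetDirection(tuple(np.asarray(direction).flatten()))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def resample_isotropic(obj: ImageVolume | RegionMask, target_spacing: float = 1.0):
    """Resample a volume or mask to an isotropic grid at ``target_spacing`` mm.

    Intensity volumes use trilinear interpolation; masks use nearest-neighbour
    so labels stay binary.  The output dimension per axis is
    ``round(dim_in * spacing_in / target)`` (round-half-up, minimum 1).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    is_mask = isinstance(obj, RegionMask)
    arr = obj.labels.astype(np.uint8) if is_mask else obj.voxels
    # round-half-up: floor(x + 0.5)
    new_size = tuple(
        max(1, int(np.floor(d * s / target_spacing + 0.5)))
        for d, s in zip(arr.shape, obj.spacing)
    )
    img = _to_sitk(arr, obj.spacing, obj.origin, obj.direction)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((target_spacing,) * 3)
    res.SetSize(new_size)
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear)
    out = _from_sitk(res.Execute(img))
    if is_mask:
        out = out > 0.5
        if obj.voxel_count > 0 and not out.any():
            warnings.warn(f"mask '{obj.name}' became empty after resampling")
        return RegionMask(out, name=obj.name, spacing=(target_spacing,) * 3,
                          origin=obj.origin, direction=obj.direction)
    return ImageVolume(out, spacing=(target_spacing,) * 3, origin=obj.origin,
                       direction=obj.direction)


def bias_correct(
    vol: ImageVolume,
    shrink_factor: int = 2,
    max_iterations: int = 50,
    convergence_threshold: float = 1e-3,
) -> ImageVolume:
    """Remove the smooth multiplicative bias field with N4 (SimpleITK).

    The correction runs on a shrunk copy for speed; the estimated log-field is
    evaluated at full resolution.  Deterministic for identical input/settings.
    """
    if np.ptp(vol.voxels) == 0:
        warnings.warn("constant volume: no structure to correct")
        return replace(vol, voxels=vol.voxels.copy())
    img = _to_sitk(vol.voxels, vol.spacing, vol.origin, vol.direction)
    mask = sitk.OtsuThreshold(img, 0, 1, 200)
    shrunk = sitk.Shrink(img, [shrink_factor] * 3)
    shrunk_mask = sitk.Shrink(mask, [shrink_factor] * 3)
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.SetMaximumNumberOfIterations([max_iterations] * 4)
    corrector.SetConvergenceThreshold(convergence_threshold)
    corrector.Execute(shrunk, shrunk_mask)
    log_field = sitk.Cast(corrector.GetLogBiasFieldAsImage(img), img.GetPixelID())
    corrected = img / sitk.Exp(log_field)
    return replace(vol, voxels=_from_sitk(corrected))


def normalize_intensity(vol: ImageVolume, support: RegionMask | None = None) -> ImageVolume:
    """Per-volume z-scoring; statistics taken within ``support`` if given."""
    sel = vol.voxels[support.labels] if support is not None else vol.voxels
    mu, sd = float(np.mean(sel)), float(np.std(sel))
    if sd == 0:
        warnings.warn("zero-variance volume: normalization skipped")
        return replace(vol, voxels=vol.voxels.copy())
    return replace(vol, voxels=(vol.voxels - mu) / sd)


def dice_coefficient(
    a: RegionMask, b: RegionMask, qc_threshold: float = DSC_QC_THRESHOLD
) -> tuple[float, bool]:
    """Dice similarity 2|A∩B|/(|A|+|B|) and a QC flag (DSC below threshold).

    Two empty masks are defined as perfectly agreeing (DSC 1.0, with warning).
    """
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise ValueError("masks must share one grid")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        warnings.warn("both masks empty: DSC defined as 1.0")
        return 1.0, False
    dsc = 2.0 * np.logical_and(a.labels, b.labels).sum() / (na + nb)
    return float(dsc), bool(dsc < qc_threshold)
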