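"""Concentric peritumoral ring masks.

Rings are non-overlapping shells at fixed millimetre distances outside the
tumor boundary, built by Euclidean distance-transform thresholding (distance
<= d voxels on a 1 mm isotropic grid) and subtraction of the inner expansion.
With the default distances [1, 3, 5] the rings are the (0,1], (1,3] and
(3,5] mm shells.  An optional valid-tissue mask clips the rings to breast
parenchyma so they never extend into air or background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, RegionMask

__all__ = ["RingSet", "build_rings", "dilate_mask", "default_body_mask", "save_ringset"]


@dataclass
class RingSet:
    rings: list[RegionMask]
    distances: list[int]
    tumor: RegionMask
    exclusion_applied: bool

    def __iter__(self):
        return iter(self.rings)


def _check_isotropic(mask: RegionMask) -> None:
    sp = mask.spacing
    if not (np.allclose(sp, sp[0]) and np.isclose(sp[0], 1.0)):
        raise ValueError(
            "build_rings requires a 1 mm isotropic grid; resample first "
            "(imaging.resample_isotropic)"
        )


def dilate_mask(mask: RegionMask, distance_vox: float) -> np.ndarray:
    """Euclidean-ball dilation: voxels within ``distance_vox`` of the mask."""
    if distance_vox <= 0:
        return mask.labels.copy()
    dist = ndimage.distance_transform_edt(~mask.labels)
    return dist <= distance_vox + 1e-9


def default_body_mask(volume: ImageVolume, fraction: float = 0.05) -> RegionMask:
    """Threshold-based valid-tissue mask: intensity above ``fraction`` of the
    robust (99th-percentile) maximum, largest connected component kept."""
    thresh = fraction * np.percentile(volume.voxels, 99)
    body = volume.voxels > thresh
    lab, n = ndimage.label(body)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        body = lab == (1 + int(np.argmax(sizes)))
    return RegionMask(body, name="body", spacing=volume.spacing,
                      origin=volume.origin, direction=volume.direction)


def build_rings(
    tumor: RegionMask,
    distances: list[int] = [1, 3, 5],
    valid_tissue: RegionMask | None = None,
    cumulative: bool = False,
) -> RingSet:
    """Build non-overlapping peritumoral shells at the given mm distances.

    ``ring_k = dilate(tumor, d_k) \\ dilate(tumor, d_{k-1})`` with d_0 = 0;
    with ``cumulative=True`` every ring instead spans (0, d_k].  Rings are
    intersected with ``valid_tissue`` when provided; a ring emptied by the
    exclusion is retained (empty) with a warning.
    """
    if tumor.voxel_count == 0:
        raise ValueError("tumor mask is empty")
    _check_isotropic(tumor)
    dist_arr = [int(d) for d in distances]
    if any(d <= 0 for d in dist_arr) or any(
        b <= a for a, b in zip(dist_arr, dist_arr[1:])
    ):
        raise ValueError("distances must be strictly increasing positive integers (mm)")
    if valid_tissue is not None and not tumor.same_grid(valid_tissue):
        raise ValueError("valid_tissue must share the tumor grid")

    edt = ndimage.distance_transform_edt(~tumor.labels)
    rings: list[RegionMask] = []
    prev = 0.0
    for d in dist_arr:
        inner = 0.0 if cumulative else prev
        shell = (edt > inner + 1e-9) & (edt <= d + 1e-9)
        if valid_tissue is not None:
            shell = shell & valid_tissue.labels
        name = f"ring{d}mm"
        if not shell.any():
            warnings.warn(f"{name} is empty after exclusion")
        rings.append(
            RegionMask(shell, name=name, spacing=tumor.spacing,
                       origin=tumor.origin, direction=tumor.direction)
        )
        prev = float(d)
    return RingSet(rings=rings, distances=dist_arr, tumor=tumor,
                   exclusion_applied=valid_tissue is not None)


def save_ringset(rs: RingSet, out_dir: str, case_id: str) -> None:
    """Write each ring as NIfTI plus a JSON sidecar recording the nominal
    distances, voxel counts and exclusion provenance."""
    import json
    from pathlib import Path

    from .imaging import write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "case_id": case_id,
        "distances_mm": rs.distances,
        "exclusion_applied": rs.exclusion_applied,
        "voxel_counts": {},
    }
    for ring in rs.rings:
        path = out / f"{case_id}_{ring.name}.nii.gz"
        write_mask(ring, str(path))
        sidecar["voxel_counts"][ring.name] = ring.voxel_count
    with open(out / f"{case_id}_rings.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
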