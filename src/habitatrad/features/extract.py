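"""Region feature extraction, signature-table assembly, and KNN imputation."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from ..imaging import ImageVolume, RegionMask
from .derived import derived_image
from .firstorder import firstorder_features
from .panel import FeaturePanelConfig, default_panel
from .shape import shape_features
from .texture import discretize, glcm_features, glrlm_features, glszm_features, ngtdm_features

__all__ = ["extract_region_features", "assemble_signature_table", "knn_impute"]

_CROP_MARGIN = 12  # voxels; generous support for the 5 mm LoG kernel


def _crop(volume: ImageVolume, region: RegionMask):
    idx = np.argwhere(region.labels)
    lo = np.maximum(idx.min(axis=0) - _CROP_MARGIN, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + _CROP_MARGIN, region.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return volume.voxels[sl], region.labels[sl]


def extract_region_features(
    volume: ImageVolume,
    region: RegionMask,
    config: FeaturePanelConfig | None = None,
) -> pd.Series:
    """Extract the configured feature panel from one region.

    Returns exactly the panel in panel order.  Statistics undefined on the
    region (texture on a sub-2-voxel region, shape on an empty one) are NaN;
    an empty region yields an all-NaN vector with a warning.
    """
    config = config if config is not None else default_panel()
    names = config.names
    if region.voxel_count == 0:
        warnings.warn(f"empty region '{region.name}': all features missing")
        return pd.Series(np.nan, index=names, name=region.name)
    if not volume.same_grid(region):
        raise ValueError("volume and region must share one grid")

    arr, mask = _crop(volume, region)
    vox_vol = float(np.prod(volume.spacing))

    # group panel entries by (image, family, distance) so each matrix is
    # computed once
    groups: dict[tuple[str, str, int], list] = {}
    for e in config.entries:
        groups.setdefault((e.image, e.family, e.distance), []).append(e)

    values: dict[str, float] = {}
    img_cache: dict[str, np.ndarray] = {}
    disc_cache: dict[str, tuple[np.ndarray, int]] = {}

    def get_image(img_name: str) -> np.ndarray:
        if img_name not in img_cache:
            img_cache[img_name] = derived_image(arr, img_name, volume.spacing)
        return img_cache[img_name]

    def get_disc(img_name: str):
        if img_name not in disc_cache:
            disc_cache[img_name] = discretize(get_image(img_name), mask, config.bin_width)
        return disc_cache[img_name]

    for (img, family, dist), entries in groups.items():
        if family == "shape":
            feats = shape_features(mask, volume.spacing)
        elif family == "firstorder":
            feats = firstorder_features(get_image(img)[mask], vox_vol, config.bin_width)
        else:
            disc, ng = get_disc(img)
            if family == "glcm":
                feats = glcm_features(disc, ng, distance=dist, names=[e.feature for e in entries])
            elif family == "glrlm":
                feats = glrlm_features(disc, ng)
            elif family == "glszm":
                feats = glszm_features(disc, ng)
            elif family == "ngtdm":
                feats = ngtdm_features(disc, ng)
            else:
                raise ValueError(f"unknown feature family: {family}")
        for e in entries:
            values[e.name] = feats[e.feature]

    out = pd.Series([values[n] for n in names], index=names, name=region.name)
    out[~np.isfinite(out.to_numpy(dtype=float))] = np.nan
    return out


def assemble_signature_table(per_region: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-region feature tables into one region-prefixed table.

    ``per_region`` maps a region tag (e.g. ``H1``, ``ring1mm``, ``tumor``) to
    a cases x P table; all tables must share the panel (columns) and cases.
    The habitat signature over three regions of a P-feature panel therefore
    has 3P columns.
    """
    if not per_region:
        raise ValueError("no regions supplied")
    tables = list(per_region.values())
    ref = tables[0]
    for t in tables[1:]:
        if list(t.columns) != list(ref.columns) or not t.index.equals(ref.index):
            raise ValueError("all regions must share panel columns and cases")
    parts = [t.add_prefix(f"{tag}_") for tag, t in per_region.items()]
    return pd.concat(parts, axis=1)


def knn_impute(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute missing cells by the mean of the k nearest cases.

    Distances are Euclidean over the z-scored features observed in both
    cases; imputation happens on the z-scored scale and is mapped back, so
    each filled cell is the neighbour mean of that column.  Columns with no
    observed values are dropped with a warning.
    """
    if not table.isna().any().any():
        return table.copy()
    all_missing = table.columns[table.isna().all()]
    if len(all_missing):
        warnings.warn(f"dropping {len(all_missing)} entirely-missing columns")
        table = table.drop(columns=all_missing)
    mu = table.mean()
    sd = table.std(ddof=0).replace(0.0, 1.0)
    z = (table - mu) / sd
    imputed = KNNImputer(n_neighbors=k).fit_transform(z.to_numpy())
    out = pd.DataFrame(imputed, index=table.index, columns=table.columns) * sd + mu
    # observed cells unchanged by construction; enforce exactly
    out = out.where(table.isna(), table)
    return out
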