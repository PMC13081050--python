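"""Feature-panel configuration.

A panel is an explicit, ordered enumeration of fully qualified feature names
(``{image}_{family}_{feature}``), each mapping to one computation.  The
packaged default panel has exactly 1,547 entries per region:

* 14 shape descriptors (original geometry);
* 18 first-order statistics on each of 17 derived images (306);
* the four texture families (24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM = 61)
  at pixel distance 1 on each of the 17 derived images (1,037);
* a reduced 19-statistic GLCM set at pixel distance 2 on the 10
  least-smoothed derived images — original, the eight wavelet sub-bands and
  the 1 mm LoG (190).

Any other enumeration may be supplied; the extractor returns exactly the
configured panel in configured order.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .derived import DERIVED_IMAGE_NAMES, LOG_NAMES, WAVELET_NAMES
from .firstorder import FIRSTORDER_NAMES
from .shape import SHAPE_NAMES
from .texture import (
    GLCM_NAMES,
    GLCM_REDUCED_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
)

__all__ = ["PanelEntry", "FeaturePanelConfig", "default_panel", "small_panel"]

PANEL_VERSION = "1.0"


@dataclass(frozen=True)
class PanelEntry:
    image: str      # derived image name
    family: str     # shape | firstorder | glcm | glcm-d2 | glrlm | glszm | ngtdm
    feature: str
    distance: int = 1  # pixel distance for directional families

    @property
    def name(self) -> str:
        fam = self.family if self.distance == 1 or self.family not in ("glcm",) else f"{self.family}-d{self.distance}"
        return f"{self.image}_{fam}_{self.feature}"


@dataclass
class FeaturePanelConfig:
    entries: list[PanelEntry]
    bin_width: float = 0.25
    version: str = PANEL_VERSION

    def __post_init__(self) -> None:
        names = self.names
        if len(names) != len(set(names)):
            raise ValueError("panel feature names must be unique")
        for e in self.entries:
            if e.family == "shape" and e.image != "original":
                raise ValueError("shape features attach to the original geometry only")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_yaml(self, path: str) -> None:
        obj = {
            "version": self.version,
            "bin_width": self.bin_width,
            "entries": [
                {"image": e.image, "family": e.family, "feature": e.feature, "distance": e.distance}
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(obj, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "FeaturePanelConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        return cls(
            entries=[PanelEntry(**e) for e in obj["entries"]],
            bin_width=obj.get("bin_width", 0.25),
            version=obj.get("version", PANEL_VERSION),
        )


_FAMILY_FEATURES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def default_panel(bin_width: float = 0.25) -> FeaturePanelConfig:
    """The packaged 1,547-feature panel (see module docstring)."""
    entries: list[PanelEntry] = [PanelEntry("original", "shape", f) for f in SHAPE_NAMES]
    for img in DERIVED_IMAGE_NAMES:
        entries += [PanelEntry(img, "firstorder", f) for f in FIRSTORDER_NAMES]
    for img in DERIVED_IMAGE_NAMES:
        for fam, feats in _FAMILY_FEATURES.items():
            entries += [PanelEntry(img, fam, f) for f in feats]
    for img in ["original", *WAVELET_NAMES, LOG_NAMES[0]]:
        entries += [PanelEntry(img, "glcm", f, distance=2) for f in GLCM_REDUCED_NAMES]
    return FeaturePanelConfig(entries=entries, bin_width=bin_width)


def small_panel(bin_width: float = 0.25) -> FeaturePanelConfig:
    """A compact panel (shape + original-image first-order/GLCM/NGTDM) for
    quick experiments and small synthetic studies."""
    entries = [PanelEntry("original", "shape", f) for f in SHAPE_NAMES]
    entries += [PanelEntry("original", "firstorder", f) for f in FIRSTORDER_NAMES]
    entries += [PanelEntry("original", "glcm", f) for f in GLCM_NAMES]
    entries += [PanelEntry("original", "ngtdm", f) for f in NGTDM_NAMES]
    return FeaturePanelConfig(entries=entries, bin_width=bin_width)
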