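"""Run configuration: one config per study, serializable to YAML.

Defaults follow the standard protocol for this analysis: 100 um axial
sections, a 1% variation borderline sustained over 3 section pairs, a
900 um (100-slice at 9 um) mid-diaphysis window, a 990 um (110-slice)
distal-epiphysis window, and alpha = 0.05 for all tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .segmentation import SegmentationParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    spacing_um: tuple[float, float, float] | None = None
    flip_orientation: bool = False  # set when the stack runs distal -> proximal
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    section_thickness_um: float = 100.0
    variation_threshold_pct: float = 1.0
    persistence: int = 3
    mid_diaphysis_window_um: float = 900.0    # 100 slices at 9 um
    distal_epiphysis_window_um: float = 990.0  # 110 slices at 9 um
    ct_th_mode: str = "slice"
    exclude_samples: list = field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["spacing_um"] is not None:
            d["spacing_um"] = list(d["spacing_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        if isinstance(seg, dict):
            seg = SegmentationParams(**seg)
        spacing = d.pop("spacing_um", None)
        if spacing is not None:
            spacing = tuple(float(s) for s in spacing)
        return cls(spacing_um=spacing, segmentation=seg, **d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
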