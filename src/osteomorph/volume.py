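"""In-memory containers for micro-CT volumes.

The package works on reconstructed grayscale volumes of long bones whose
voxel values are linear attenuation coefficients in mm^-1 (a proxy for
mineral density at fixed photon energy).  By convention axis 0 of every
array is the bone's longitudinal axis, with the proximal end at index 0;
spacings are given per axis in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AttenuationVolume", "TissueLabelVolume", "BACKGROUND", "CORTICAL", "CANCELLOUS"]

BACKGROUND = 0
CORTICAL = 1
CANCELLOUS = 2


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacing values must be > 0, got {spacing}")
    return spacing


@dataclass
class AttenuationVolume:
    """A 3D scalar field of linear attenuation (mm^-1).

    Parameters
    ----------
    data:
        3D array, axis 0 = longitudinal (slice) axis, proximal end at index 0.
    spacing:
        Per-axis voxel size in micrometres, ordered like the array axes.
    allow_negative:
        Reconstruction noise can produce slightly negative attenuation.  If
        False (default) negative values are clipped to zero on construction;
        if True they are kept as-is.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    allow_negative: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("attenuation values must be finite")
        self.spacing = _check_spacing(self.spacing)
        if not self.allow_negative and (self.data < 0).any():
            self.data = np.clip(self.data, 0.0, None)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def slice_spacing_um(self) -> float:
        """Spacing along the bone axis (axis 0), in micrometres."""
        return self.spacing[0]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def length_um(self) -> float:
        """Axial extent of the stack in micrometres."""
        return self.shape[0] * self.spacing[0]

    def flipped(self) -> "AttenuationVolume":
        """Volume with the proximal/distal orientation reversed."""
        return AttenuationVolume(self.data[::-1].copy(), self.spacing,
                                 allow_negative=True)


@dataclass
class TissueLabelVolume:
    """Per-voxel tissue label: 0 background, 1 cortical, 2 cancellous."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, CORTICAL, CANCELLOUS])
        if bad.size:
            raise ValueError(f"labels outside {{0,1,2}}: {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def cortical_mask(self) -> np.ndarray:
        return self.labels == CORTICAL

    @property
    def cancellous_mask(self) -> np.ndarray:
        return self.labels == CANCELLOUS

    @property
    def bone_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def flipped(self) -> "TissueLabelVolume":
        return TissueLabelVolume(self.labels[::-1].copy(), self.spacing)
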