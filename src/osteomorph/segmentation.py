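"""Bone binarization and cortical/cancellous separation.

A single global Otsu threshold separates mineralized tissue from soft
tissue/background for the whole sample.  Cortical bone (the compact outer
shell) is then isolated per transverse slice with a fixed, deterministic
morphological rule — closing to seal the shell, opening to strip thin
trabecular bridges, then keeping the largest connected component restricted
to original bone voxels — and everything else mineralized is cancellous.
The subcortical (endocortical-fill) mask is the filled interior of the
cortical shell minus the shell itself; its volume is Sc.V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import AttenuationVolume, TissueLabelVolume, CORTICAL, CANCELLOUS

__all__ = [
    "SegmentationParams", "otsu_threshold", "binarize",
    "split_cortical_cancellous", "endocortical_fill", "segment_volume",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Tunable knobs of the cortical/cancellous split.

    Radii are in micrometres and converted to voxels through the volume
    spacing.  ``min_component_volume_um3=None`` means 10 voxel volumes:
    bone specks smaller than that are treated as reconstruction noise and
    relabeled background.
    """

    otsu_bins: int = 256
    morph_radius_close_um: float = 54.0
    morph_radius_open_um: float = 40.0
    min_component_volume_um3: float | None = None

    def __post_init__(self):
        if self.otsu_bins < 2:
            raise ValueError("otsu_bins must be >= 2")
        if self.morph_radius_close_um < 0 or self.morph_radius_open_um < 0:
            raise ValueError("morphological radii must be >= 0")
        if (self.min_component_volume_um3 is not None
                and self.min_component_volume_um3 < 0):
            raise ValueError("min_component_volume_um3 must be >= 0")

    def min_component_voxels(self, voxel_volume_um3: float) -> int:
        if self.min_component_volume_um3 is None:
            return 10
        return int(np.ceil(self.min_component_volume_um3 / voxel_volume_um3))


def otsu_threshold(volume, bins: int = 256) -> float:
    """Global Otsu threshold (mm^-1) over the whole-volume histogram.

    Returns the bin edge maximizing the between-class variance; one
    threshold per sample, never per slice.  Raises on a constant volume.
    """
    data = volume.data if isinstance(volume, AttenuationVolume) else np.asarray(volume)
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise ValueError("cannot threshold a constant volume")
    counts, edges = np.histogram(data.reshape(-1), bins=bins, range=(vmin, vmax))
    return _otsu_from_histogram(counts, edges)


def _otsu_from_histogram(counts: np.ndarray, edges: np.ndarray) -> float:
    """Between-class-variance maximizer over all interior bin edges.

    Candidate threshold k places bins [0..k-1] in the low class; vectorized
    equivalent of the exhaustive search over every cut point.
    """
    counts = np.asarray(counts, dtype=np.float64)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)
    total = w0[-1]
    w1 = total - w0
    m0 = np.cumsum(counts * centers)
    mtot = m0[-1]
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    if not valid.any():
        raise ValueError("histogram has fewer than two occupied bins")
    mu0 = np.where(w0[:-1] > 0, m0[:-1] / np.maximum(w0[:-1], 1e-300), 0.0)
    mu1 = np.where(w1[:-1] > 0, (mtot - m0[:-1]) / np.maximum(w1[:-1], 1e-300), 0.0)
    sigma_b = w0[:-1] * w1[:-1] * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    # ties (an empty valley between well-separated modes) are broken at the
    # plateau middle, keeping the threshold clear of both modes
    best = sigma_b.max()
    tied = np.flatnonzero(sigma_b >= best * (1 - 1e-12))
    k = int(tied[len(tied) // 2])
    return float(edges[k + 1])


def binarize(volume, threshold: float) -> np.ndarray:
    """Bone mask: voxel is bone iff attenuation > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = volume.data if isinstance(volume, AttenuationVolume) else np.asarray(volume)
    return data > threshold


def _disk(radius_vox: int) -> np.ndarray:
    if radius_vox <= 0:
        return np.ones((1, 1), dtype=bool)
    r = radius_vox
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def _radius_vox(radius_um: float, spacing_xy: float) -> int:
    return int(round(radius_um / spacing_xy)) if radius_um > 0 else 0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.reshape(-1))
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def split_cortical_cancellous(bone_mask: np.ndarray, spacing,
                              params: SegmentationParams | None = None,
                              ) -> TissueLabelVolume:
    """Separate the compact shell (cortical) from interior lattice (cancellous).

    Per transverse slice: close with ``morph_radius_close_um``, open with
    ``morph_radius_open_um``, keep the largest connected component, and
    restrict to original bone voxels.  Remaining bone is cancellous, so
    cortical + cancellous partition the (denoised) bone mask exactly.
    Connected bone components smaller than the minimum component volume are
    relabeled background first.
    """
    params = params or SegmentationParams()
    bone_mask = np.asarray(bone_mask, dtype=bool)
    if bone_mask.ndim != 3:
        raise ValueError("bone mask must be 3D")
    if not bone_mask.any():
        raise ValueError("bone mask is empty")
    spacing = tuple(float(s) for s in spacing)

    # denoise: drop 3D specks below the minimum component volume
    min_vox = params.min_component_voxels(float(np.prod(spacing)))
    if min_vox > 1:
        lab, n = ndimage.label(bone_mask)
        if n > 1:
            sizes = np.bincount(lab.reshape(-1))
            keep = sizes >= min_vox
            keep[0] = False
            bone_mask = keep[lab]

    sp_xy = min(spacing[1], spacing[2])
    r_close = _radius_vox(params.morph_radius_close_um, sp_xy)
    r_open = _radius_vox(params.morph_radius_open_um, sp_xy)
    disk_close, disk_open = _disk(r_close), _disk(r_open)

    labels = np.zeros(bone_mask.shape, dtype=np.uint8)
    for z in range(bone_mask.shape[0]):
        sl = bone_mask[z]
        if not sl.any():
            log.debug("slice %d: no bone voxels, labeled background", z)
            continue
        work = sl
        if r_close > 0:
            work = ndimage.binary_closing(work, structure=disk_close)
        if r_open > 0:
            work = ndimage.binary_opening(work, structure=disk_open)
        cortical = _largest_component(work) & sl if work.any() else np.zeros_like(sl)
        labels[z][cortical] = CORTICAL
        labels[z][sl & ~cortical] = CANCELLOUS
    return TissueLabelVolume(labels, spacing)


def endocortical_fill(labels: TissueLabelVolume,
                      close_radius_um: float | None = None,
                      ) -> tuple[np.ndarray, list[int]]:
    """Subcortical (Sc) mask: per-slice filled interior of the cortical shell.

    Returns ``(sc_mask, flagged_slices)``.  A slice whose cortex encloses no
    interior on the first pass is re-tried after a closing at twice the
    configured closing radius; if the shell is still open the slice
    contributes no Sc voxels and is flagged rather than overestimated.
    """
    if close_radius_um is None:
        close_radius_um = 2.0 * SegmentationParams().morph_radius_close_um
    ct = labels.cortical_mask
    sp_xy = min(labels.spacing[1], labels.spacing[2])
    disk = _disk(max(1, _radius_vox(close_radius_um, sp_xy)))
    sc = np.zeros(ct.shape, dtype=bool)
    flagged: list[int] = []
    for z in range(ct.shape[0]):
        shell = ct[z]
        if not shell.any():
            continue
        interior = ndimage.binary_fill_holes(shell) & ~shell
        if not interior.any():
            closed = ndimage.binary_closing(shell, structure=disk)
            interior = ndimage.binary_fill_holes(closed) & ~closed
            if interior.any():
                flagged.append(z)
                log.warning("slice %d: cortex not closed; filled after 2x closing", z)
            else:
                # solid cross-section or irrecoverably open shell: Sc stays empty
                continue
        sc[z] = interior
    return sc, flagged


def segment_volume(volume: AttenuationVolume,
                   params: SegmentationParams | None = None,
                   ) -> tuple[TissueLabelVolume, float]:
    """Otsu -> binarize -> cortical/cancellous split; returns (labels, threshold)."""
    params = params or SegmentationParams()
    thr = otsu_threshold(volume, bins=params.otsu_bins)
    mask = binarize(volume, thr)
    return split_cortical_cancellous(mask, volume.spacing, params), thr
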