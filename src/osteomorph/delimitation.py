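"""Delimitation of long-bone regions from the axial attenuation profile.

The bone is virtually transected into thin transverse sections (100 um by
default) and the mean cortical attenuation mu.Ct_i of each section is
computed.  The percent change between adjacent sections,

    Variation_i = 100 * (mu.Ct_i - mu.Ct_{i-1}) / mu.Ct_{i-1}   [%],

is near zero along the diaphysis, where cortical density is uniform, and
exceeds 1% per section inside the epiphysis+metaphysis (EM) zones, where
density ramps toward the bone ends.  The diaphysis is therefore recovered
as the maximal central run of sub-threshold variations; its flanks are the
proximal and distal EM-zone borderlines.  A second pass splits the
diaphysis at the change point of the axial cancellous-fraction profile into
a proximal zone A (nearly trabeculae-free) and a distal zone B.

The |Variation| > threshold criterion is applied to the absolute value:
attenuation falls toward the proximal end and rises toward the distal end,
so the sign of the crossing depends only on scan orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import endocortical_fill
from .volume import AttenuationVolume, TissueLabelVolume

__all__ = [
    "AxialProfile", "VariationSeries", "RegionSegmentation", "NoDiaphysisError",
    "axial_profile", "variation_series", "detect_boundaries",
    "boundary_offsets", "subdivide_diaphysis", "split_em_zone_at_plate",
    "delimit",
]


class NoDiaphysisError(RuntimeError):
    """No sustained run of sub-threshold variations was found."""

    def __init__(self, message, variation=None):
        super().__init__(message)
        self.variation = variation


@dataclass
class AxialProfile:
    """Per-section axial records, ordered proximal -> distal.

    Arrays are aligned by section index.  ``mean_ct_mu`` is NaN where a
    section contains no cortical voxels; ``cn_fraction`` (sectionwise
    Cn.BV/Sc.V) is NaN where the subcortical space is empty.
    """

    z_start_um: np.ndarray
    z_end_um: np.ndarray
    mean_ct_mu: np.ndarray
    cn_fraction: np.ndarray
    n_cortical_voxels: np.ndarray
    slices_per_section: int
    slice_spacing_um: float

    @property
    def n_sections(self) -> int:
        return len(self.mean_ct_mu)

    @property
    def length_um(self) -> float:
        return float(self.z_end_um[-1])

    def section_slice_bounds(self, i: int) -> tuple[int, int]:
        """Half-open slice range [z0, z1) covered by section ``i``."""
        z0 = i * self.slices_per_section
        z1 = int(round(self.z_end_um[i] / self.slice_spacing_um))
        return z0, z1


@dataclass
class VariationSeries:
    """Variation_i aligned to sections: values[i] compares section i with the
    previous section that has a defined cortical mean; values[0] is NaN."""

    values: np.ndarray

    def defined(self) -> np.ndarray:
        return np.flatnonzero(np.isfinite(self.values))


@dataclass
class RegionSegmentation:
    """Borderline section indices plus the derived percent offsets.

    ``prox_em_end`` is the first diaphyseal section, ``dia_end`` the last;
    ``ab_split`` (when computed) is the first section of diaphyseal zone B.
    Offsets are the borderline distances from the respective bone ends as a
    percentage of sample length.
    """

    prox_em_end: int
    dia_end: int
    ab_split: int | None = None
    prox_offset_pct: float = float("nan")
    dist_offset_pct: float = float("nan")

    def to_dict(self, profile: AxialProfile | None = None) -> dict:
        out = {
            "prox_em_end_section": int(self.prox_em_end),
            "dia_end_section": int(self.dia_end),
            "ab_split_section": None if self.ab_split is None else int(self.ab_split),
            "prox_offset_pct": float(self.prox_offset_pct),
            "dist_offset_pct": float(self.dist_offset_pct),
        }
        if profile is not None:
            out["prox_boundary_um"] = float(profile.z_start_um[self.prox_em_end])
            out["dist_boundary_um"] = float(profile.z_end_um[self.dia_end])
            out["prox_boundary_slice"] = int(
                profile.section_slice_bounds(self.prox_em_end)[0])
            out["dist_boundary_slice"] = int(
                profile.section_slice_bounds(self.dia_end)[1])
            if self.ab_split is not None:
                out["ab_split_um"] = float(profile.z_start_um[self.ab_split])
                out["ab_split_slice"] = int(
                    profile.section_slice_bounds(self.ab_split)[0])
        return out


def axial_profile(volume: AttenuationVolume, labels: TissueLabelVolume,
                  section_thickness_um: float = 100.0,
                  sc_mask: np.ndarray | None = None) -> AxialProfile:
    """Group slices into sections and profile cortical attenuation and
    cancellous fraction along the bone axis.

    Sections are ceil(thickness / slice spacing) whole slices — no
    resampling, so voxel counts stay exact for the fraction denominators.
    The last section may be shorter.
    """
    if volume.shape != labels.shape:
        raise ValueError(f"volume {volume.shape} and labels {labels.shape} differ")
    h = volume.slice_spacing_um
    if section_thickness_um < h:
        raise ValueError("section thickness must be >= one slice spacing")
    sps = int(np.ceil(section_thickness_um / h))
    nz = volume.shape[0]
    n_sections = int(np.ceil(nz / sps))

    ct = labels.cortical_mask
    cn = labels.cancellous_mask
    if not ct.any():
        raise ValueError("no cortical voxels anywhere in the volume")
    if sc_mask is None:
        sc_mask, _ = endocortical_fill(labels)

    # per-slice sums, then grouped into sections
    ct_sum = np.where(ct, volume.data, 0.0).sum(axis=(1, 2))
    ct_n = ct.sum(axis=(1, 2)).astype(np.int64)
    cn_n = cn.sum(axis=(1, 2)).astype(np.int64)
    sc_n = (sc_mask | cn).sum(axis=(1, 2)).astype(np.int64)

    def group(a):
        pad = n_sections * sps - nz
        a = np.concatenate([a, np.zeros(pad, dtype=a.dtype)])
        return a.reshape(n_sections, sps).sum(axis=1)

    g_ct_sum, g_ct_n = group(ct_sum), group(ct_n)
    g_cn_n, g_sc_n = group(cn_n), group(sc_n)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_mu = np.where(g_ct_n > 0, g_ct_sum / np.maximum(g_ct_n, 1), np.nan)
        cn_frac = np.where(g_sc_n > 0, g_cn_n / np.maximum(g_sc_n, 1), np.nan)

    z_start = np.arange(n_sections) * sps * h
    z_end = np.minimum((np.arange(n_sections) + 1) * sps, nz) * h
    return AxialProfile(z_start, z_end, mean_mu, cn_frac, g_ct_n, sps, h)


def variation_series(profile: AxialProfile) -> VariationSeries:
    """Percent change of mean cortical attenuation between consecutive
    defined sections (signed)."""
    mu = profile.mean_ct_mu
    defined = np.flatnonzero(np.isfinite(mu))
    if defined.size < 2:
        raise ValueError("need >= 2 sections with defined cortical mean")
    values = np.full(profile.n_sections, np.nan)
    prev = defined[0]
    for i in defined[1:]:
        if mu[prev] <= 0:
            raise ValueError(f"non-physical cortical mean {mu[prev]} in section {prev}")
        values[i] = 100.0 * (mu[i] - mu[prev]) / mu[prev]
        prev = i
    return VariationSeries(values)


def detect_boundaries(variation: VariationSeries, threshold_pct: float = 1.0,
                      persistence: int = 3) -> tuple[int, int]:
    """Locate the diaphysis as the maximal central sub-threshold run.

    A section pair is "quiet" when |Variation_i| <= threshold.  Among all
    maximal runs of >= ``persistence`` consecutive quiet pairs the longest
    is taken (ties resolved toward the series centre), so an isolated quiet
    pair inside an EM-zone cannot trigger a borderline.  Returns
    ``(prox_em_end, dia_end)``: the first and last section of the plateau;
    each borderline plane is the shared face between the flanking
    above-threshold pair and the plateau.
    """
    v = variation.values
    n = len(v)
    if n == 0:
        raise NoDiaphysisError("empty variation series", variation)
    quiet = np.isfinite(v) & (np.abs(v) <= threshold_pct)
    runs: list[tuple[int, int]] = []  # inclusive pair-index ranges
    i = 0
    while i < n:
        if quiet[i]:
            j = i
            while j + 1 < n and quiet[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    runs = [(a, b) for a, b in runs if b - a + 1 >= persistence]
    if not runs:
        raise NoDiaphysisError(
            f"no diaphysis detected: no run of >= {persistence} consecutive "
            f"|Variation| <= {threshold_pct}% pairs", variation)
    centre = (n - 1) / 2.0
    runs.sort(key=lambda r: (-(r[1] - r[0]), abs((r[0] + r[1]) / 2.0 - centre)))
    a, b = runs[0]
    # pair i compares sections (i-1, i); quiet pairs a..b span sections a-1..b
    return max(a - 1, 0), b


def boundary_offsets(seg: RegionSegmentation, profile: AxialProfile,
                     sample_length_um: float | None = None,
                     ) -> tuple[float, float]:
    """Borderline distances from the bone ends, as % of sample length."""
    length = profile.length_um if sample_length_um is None else float(sample_length_um)
    if length <= 0:
        raise ValueError("sample length must be > 0")
    if not (0 <= seg.prox_em_end <= seg.dia_end < profile.n_sections):
        raise ValueError("boundaries outside profile extent")
    prox = 100.0 * profile.z_start_um[seg.prox_em_end] / length
    dist = 100.0 * (length - profile.z_end_um[seg.dia_end]) / length
    return float(prox), float(dist)


def _sse_split(series: np.ndarray) -> np.ndarray:
    """SSE of the two-segment piecewise-constant fit for every split point k
    (segment A = series[:k], B = series[k:]), k = 1..m-1."""
    m = len(series)
    out = np.empty(m - 1)
    for k in range(1, m):
        a, b = series[:k], series[k:]
        out[k - 1] = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return out


def subdivide_diaphysis(profile: AxialProfile, seg: RegionSegmentation,
                        ) -> RegionSegmentation:
    """Split the diaphysis into proximal zone A and distal zone B.

    The split is the change point minimizing the two-segment
    piecewise-constant SSE of the cancellous-fraction series over the
    diaphysis, constrained so zone A (proximal) has the lower mean — the
    proximal shaft holds cancellous bone only as occasional inclusions.
    The EM borderlines found in the first pass are left untouched.
    Returns a new segmentation with ``ab_split`` = first section of zone B.
    """
    lo, hi = seg.prox_em_end, seg.dia_end
    series = profile.cn_fraction[lo:hi + 1].copy()
    series[~np.isfinite(series)] = 0.0
    m = len(series)
    if m < 4:
        raise ValueError("diaphysis must span >= 4 sections to subdivide")
    if np.allclose(series, series[0]):
        import warnings
        warnings.warn("constant cancellous-fraction series; A/B split at midpoint")
        k = m // 2
    else:
        sse = _sse_split(series)
        order = np.argsort(sse, kind="stable")
        k = None
        for idx in order:
            kk = idx + 1
            if series[:kk].mean() < series[kk:].mean():
                k = kk
                break
        if k is None:
            import warnings
            warnings.warn("no split with proximal mean < distal mean; "
                          "using unconstrained SSE minimum")
            k = int(order[0]) + 1
    return RegionSegmentation(seg.prox_em_end, seg.dia_end, ab_split=int(lo + k),
                              prox_offset_pct=seg.prox_offset_pct,
                              dist_offset_pct=seg.dist_offset_pct)


def split_em_zone_at_plate(labels: TissueLabelVolume, seg: RegionSegmentation,
                           profile: AxialProfile, plate_slice: int,
                           zone: str = "proximal",
                           sc_mask: np.ndarray | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Partition an EM-zone's subcortical volume into epiphysis and
    metaphysis at a user-supplied epiphyseal-plate slice.

    The plate is an anatomical reference the tool does not detect itself.
    Returns ``(epiphysis_mask, metaphysis_mask)``; the two masks are
    disjoint and together cover the EM-zone subcortical volume exactly.
    """
    if sc_mask is None:
        sc_mask, _ = endocortical_fill(labels)
    sc_like = sc_mask | labels.cancellous_mask
    nz = labels.shape[0]
    if zone == "proximal":
        z0, z1 = 0, profile.section_slice_bounds(seg.prox_em_end)[0]
        epi_range = (z0, plate_slice)
        meta_range = (plate_slice, z1)
    elif zone == "distal":
        z0, z1 = profile.section_slice_bounds(seg.dia_end)[1], nz
        meta_range = (z0, plate_slice)
        epi_range = (plate_slice, z1)
    else:
        raise ValueError(f"zone must be 'proximal' or 'distal', got {zone!r}")
    if not (z0 <= plate_slice <= z1):
        raise ValueError(f"plate slice {plate_slice} outside {zone} EM-zone "
                         f"slices [{z0}, {z1}]")
    epi = np.zeros_like(sc_like)
    meta = np.zeros_like(sc_like)
    epi[epi_range[0]:epi_range[1]] = sc_like[epi_range[0]:epi_range[1]]
    meta[meta_range[0]:meta_range[1]] = sc_like[meta_range[0]:meta_range[1]]
    return epi, meta


def delimit(volume: AttenuationVolume, labels: TissueLabelVolume,
            section_thickness_um: float = 100.0, threshold_pct: float = 1.0,
            persistence: int = 3, subdivide: bool = True,
            sc_mask: np.ndarray | None = None,
            ) -> tuple[RegionSegmentation, AxialProfile, VariationSeries]:
    """Full delimitation: profile -> variation -> borderlines -> A/B split."""
    profile = axial_profile(volume, labels, section_thickness_um, sc_mask=sc_mask)
    variation = variation_series(profile)
    prox, dia = detect_boundaries(variation, threshold_pct, persistence)
    seg = RegionSegmentation(prox, dia)
    seg.prox_offset_pct, seg.dist_offset_pct = boundary_offsets(seg, profile)
    if subdivide and dia - prox + 1 >= 4:
        seg = subdivide_diaphysis(profile, seg)
    return seg, profile, variation
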