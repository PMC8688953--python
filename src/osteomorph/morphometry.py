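"""3D bone morphometry: whole-sample, regional, trabecular and cortical
cross-section parameters.

Computed quantities follow the standard bone-morphometry nomenclature:

* Sa.Le — sample length (mm), axial extent of bone voxels.
* TV / BV / BV-TV — total volume of the examined sample (per-slice filled
  outer contour of the bone, marrow cavity included), bone volume, and
  their ratio.  mu.B is the median attenuation over all bone voxels.
* Per region: median cortical/cancellous attenuation (mu.Ct, mu.Cn),
  cortical volume fraction Ct.BV/TV, cancellous fraction Cn.BV/Sc.V of the
  subcortical volume, and Sc.V itself.
* Tb.Th / Tb.Sp / Tb.N — model-independent trabecular thickness and
  separation (maximal-inscribed-sphere means) and number, Tb.N = 1/(Tb.Th
  + Tb.Sp), conventionally over the distal-epiphysis cancellous
  compartment (990 um window).
* Tt.Ar / Ct.Ar / Ct.Ar/Tt.Ar / Ct.Th — mean total and cortical
  cross-sectional areas over a mid-diaphysis window (900 um) and mean
  cortical thickness, twice the mean distance transform sampled on the
  cortical medial surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .delimitation import AxialProfile, RegionSegmentation
from .segmentation import endocortical_fill
from .thickness import local_thickness
from .volume import AttenuationVolume, TissueLabelVolume

__all__ = [
    "WholeSampleMetrics", "RegionalMetrics", "TrabecularMetrics",
    "CorticalCrossSection", "MorphometryReport",
    "whole_sample_metrics", "regional_metrics", "trabecular_metrics",
    "cortical_cross_section", "region_slice_range", "morphometry_report",
]

REGIONS = ("whole", "prox_em", "diaphysis", "dia_A", "dia_B", "dist_em")


@dataclass
class WholeSampleMetrics:
    sa_le_mm: float
    tv_mm3: float
    bv_mm3: float
    bv_tv: float
    mu_b: float


@dataclass
class RegionalMetrics:
    mu_ct: float
    mu_cn: float
    ct_bv_tv: float
    cn_bv_scv: float
    sc_v_mm3: float


@dataclass
class TrabecularMetrics:
    tb_th_mm: float
    tb_sp_mm: float
    tb_n_per_mm: float


@dataclass
class CorticalCrossSection:
    tt_ar_mm2: float
    ct_ar_mm2: float
    ct_ar_tt_ar: float
    ct_th_mm: float
    degenerate: bool = False  # True when the shaft has no lumen


def _filled_slices(mask: np.ndarray) -> np.ndarray:
    """Per-slice filled outer contour of a 3D binary mask."""
    out = np.zeros_like(mask)
    for z in range(mask.shape[0]):
        if mask[z].any():
            out[z] = ndimage.binary_fill_holes(mask[z])
    return out


def whole_sample_metrics(volume: AttenuationVolume, labels: TissueLabelVolume,
                         ) -> WholeSampleMetrics:
    """Sa.Le, TV, BV, BV/TV and median bone attenuation for the whole sample."""
    bone = labels.bone_mask
    if not bone.any():
        raise ValueError("label volume contains no bone")
    zs = np.flatnonzero(bone.any(axis=(1, 2)))
    sa_le_mm = (zs[-1] - zs[0] + 1) * labels.spacing[0] / 1000.0
    vox_mm3 = labels.voxel_volume_um3 * 1e-9
    tv = int(_filled_slices(bone).sum()) * vox_mm3
    bv = int(bone.sum()) * vox_mm3
    mu_b = float(np.median(volume.data[bone]))
    return WholeSampleMetrics(float(sa_le_mm), float(tv), float(bv),
                              float(bv / tv), mu_b)


def region_slice_range(seg: RegionSegmentation, profile: AxialProfile,
                       region: str, nz: int) -> tuple[int, int]:
    """Half-open slice range [z0, z1) of a named region."""
    prox = profile.section_slice_bounds(seg.prox_em_end)[0]
    dist = profile.section_slice_bounds(seg.dia_end)[1]
    if region == "whole":
        return 0, nz
    if region == "prox_em":
        return 0, prox
    if region == "diaphysis":
        return prox, dist
    if region == "dist_em":
        return dist, nz
    if region in ("dia_A", "dia_B"):
        if seg.ab_split is None:
            raise ValueError("segmentation has no A/B split")
        ab = profile.section_slice_bounds(seg.ab_split)[0]
        return (prox, ab) if region == "dia_A" else (ab, dist)
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def regional_metrics(volume: AttenuationVolume, labels: TissueLabelVolume,
                     seg: RegionSegmentation, profile: AxialProfile,
                     region: str, sc_mask: np.ndarray | None = None,
                     ) -> RegionalMetrics:
    """Median attenuations and volume fractions over one region.

    The entire cortical and cancellous compartments within the region's
    slice range are used.  ``cn_bv_scv`` is NaN when the region has no
    subcortical space.
    """
    if sc_mask is None:
        sc_mask, _ = endocortical_fill(labels)
    z0, z1 = region_slice_range(seg, profile, region, labels.shape[0])
    if z1 <= z0:
        raise ValueError(f"region {region!r} is empty (slices [{z0}, {z1}))")
    ct = labels.cortical_mask[z0:z1]
    cn = labels.cancellous_mask[z0:z1]
    bone = ct | cn
    data = volume.data[z0:z1]
    vox_mm3 = labels.voxel_volume_um3 * 1e-9
    tv_vox = int(_filled_slices(bone).sum())
    sc_vox = int((sc_mask[z0:z1] | cn).sum())
    mu_ct = float(np.median(data[ct])) if ct.any() else float("nan")
    mu_cn = float(np.median(data[cn])) if cn.any() else float("nan")
    ct_bv_tv = float(ct.sum() / tv_vox) if tv_vox else float("nan")
    cn_bv_scv = float(cn.sum() / sc_vox) if sc_vox else float("nan")
    return RegionalMetrics(mu_ct, mu_cn, ct_bv_tv, cn_bv_scv,
                           float(sc_vox * vox_mm3))


def _expanded_bbox(sel: np.ndarray, margins: tuple[int, ...]) -> tuple[slice, ...]:
    return tuple(slice(max(int(idx.min()) - m, 0), int(idx.max()) + 1 + m)
                 for idx, m in zip(np.nonzero(sel), margins))


def _region_mean_thickness(structure: np.ndarray, region: np.ndarray,
                           spacing, margin_um: float) -> float:
    """Mean local thickness over ``structure & region``, with the thickness
    field computed on the structure inside the region's bounding box padded
    by ``margin_um`` — so spheres are not cut off at the region border."""
    sel = structure & region
    margins = tuple(int(np.ceil(margin_um / s)) for s in spacing)
    bbox = _expanded_bbox(sel, margins)
    field = local_thickness(structure[bbox], spacing)
    return float(field[sel[bbox]].mean())


def trabecular_metrics(labels: TissueLabelVolume, region_mask: np.ndarray,
                       sc_mask: np.ndarray | None = None,
                       context_margin_um: float = 300.0) -> TrabecularMetrics:
    """Tb.Th, Tb.Sp and Tb.N over the cancellous compartment of a region.

    Tb.Th is the volume-weighted mean maximal-inscribed-sphere diameter of
    the cancellous voxels; Tb.Sp the same over the non-bone space within
    the subcortical region; Tb.N = 1 / (Tb.Th + Tb.Sp).  Thickness fields
    see the structure up to ``context_margin_um`` beyond the region, so
    region borders do not truncate the inscribed spheres.
    """
    if sc_mask is None:
        sc_mask, _ = endocortical_fill(labels)
    region_mask = np.asarray(region_mask, dtype=bool)
    cn_all = labels.cancellous_mask
    if not (cn_all & region_mask).any():
        raise ValueError("region contains no cancellous voxels")
    space_all = (sc_mask | cn_all) & ~labels.bone_mask
    tb_th = _region_mean_thickness(cn_all, region_mask, labels.spacing,
                                   context_margin_um) / 1000.0
    if (space_all & region_mask).any():
        tb_sp = _region_mean_thickness(space_all, region_mask, labels.spacing,
                                       context_margin_um) / 1000.0
    else:
        tb_sp = float("nan")
    tb_n = 1.0 / (tb_th + tb_sp)
    return TrabecularMetrics(tb_th, tb_sp, float(tb_n))


def _slice_ct_th(ct_slice: np.ndarray, spacing_yx) -> tuple[float, int]:
    """Sum of medial-surface distance values and sample count for one slice."""
    skel = skeletonize(ct_slice)
    if not skel.any():
        return 0.0, 0
    dt = ndimage.distance_transform_edt(ct_slice, sampling=spacing_yx)
    return float(dt[skel].sum()), int(skel.sum())


def cortical_cross_section(labels: TissueLabelVolume,
                           seg: RegionSegmentation | None = None,
                           profile: AxialProfile | None = None,
                           window_slices: int | None = None,
                           window_um: float = 900.0,
                           slice_range: tuple[int, int] | None = None,
                           mode: str = "slice") -> CorticalCrossSection:
    """Tt.Ar, Ct.Ar, Ct.Ar/Tt.Ar and Ct.Th over a mid-diaphysis window.

    The window (900 um ~ 100 slices at 9 um by default) is centred at the
    diaphysis midpoint; alternatively pass an explicit ``slice_range``.
    Ct.Th = 2 x mean distance-transform value on the cortical medial
    surface, computed per slice (``mode='slice'``, default) or on the 3D
    skeleton of the window (``mode='3d'``).  A shaft without a lumen is
    flagged degenerate: the medial "surface" collapses to the centre and
    Ct.Th reports the inscribed radius.
    """
    nz = labels.shape[0]
    h = labels.spacing[0]
    if window_slices is None:
        window_slices = max(1, int(round(window_um / h)))
    if slice_range is None:
        if seg is None or profile is None:
            raise ValueError("need seg+profile or an explicit slice_range")
        z0, z1 = region_slice_range(seg, profile, "diaphysis", nz)
        mid = (z0 + z1) // 2
        w0, w1 = mid - window_slices // 2, mid - window_slices // 2 + window_slices
        if w0 < z0 or w1 > z1:
            raise ValueError(
                f"mid-diaphysis window [{w0}, {w1}) of {window_slices} slices "
                f"extends outside the diaphysis [{z0}, {z1})")
    else:
        w0, w1 = slice_range
    ct = labels.cortical_mask[w0:w1]
    bone = labels.bone_mask[w0:w1]
    n = w1 - w0
    if n <= 0 or not ct.any():
        raise ValueError("empty cortical window")
    px_mm2 = labels.spacing[1] * labels.spacing[2] * 1e-6
    tt_ar = float(_filled_slices(bone).sum()) / n * px_mm2
    ct_ar = float(ct.sum()) / n * px_mm2

    degenerate = not any(
        (ndimage.binary_fill_holes(ct[z]) & ~ct[z]).any() for z in range(n))
    if mode == "slice":
        total, count = 0.0, 0
        for z in range(n):
            s, c = _slice_ct_th(ct[z], labels.spacing[1:])
            total += s
            count += c
    elif mode == "3d":
        skel = skeletonize(ct)
        dt = ndimage.distance_transform_edt(ct, sampling=labels.spacing)
        total, count = float(dt[skel].sum()), int(skel.sum())
    else:
        raise ValueError(f"mode must be 'slice' or '3d', got {mode!r}")
    ct_th = 2.0 * total / count / 1000.0 if count else float("nan")
    return CorticalCrossSection(tt_ar, ct_ar, float(ct_ar / tt_ar), float(ct_th),
                                degenerate=degenerate)


@dataclass
class MorphometryReport:
    """The full parameter set for one sample: whole-bone block, per-region
    blocks, the distal-epiphysis trabecular block and the mid-diaphysis
    cortical block."""

    sample_id: str
    whole: WholeSampleMetrics
    regions: dict = field(default_factory=dict)
    trabecular: TrabecularMetrics | None = None
    mid_diaphysis: CorticalCrossSection | None = None

    _REGION_KEYS = {"prox_em": "ProxEM", "diaphysis": "Dia", "dia_A": "DiaA",
                    "dia_B": "DiaB", "dist_em": "DistEM", "whole": "Whole"}

    def to_flat_dict(self) -> dict:
        nan = float("nan")
        out = {
            "sample_id": self.sample_id,
            "Sa.Le": self.whole.sa_le_mm,
            "TV": self.whole.tv_mm3,
            "BV": self.whole.bv_mm3,
            "BV/TV": self.whole.bv_tv,
            "mu.B": self.whole.mu_b,
        }
        for region, prefix in self._REGION_KEYS.items():
            r = self.regions.get(region)
            out[f"{prefix}.mu.Ct"] = r.mu_ct if r else nan
            out[f"{prefix}.mu.Cn"] = r.mu_cn if r else nan
            out[f"{prefix}.Ct.BV/TV"] = r.ct_bv_tv if r else nan
            out[f"{prefix}.Cn.BV/Sc.V"] = r.cn_bv_scv if r else nan
            out[f"{prefix}.Sc.V"] = r.sc_v_mm3 if r else nan
        t = self.trabecular
        out["Tb.Th"] = t.tb_th_mm if t else nan
        out["Tb.Sp"] = t.tb_sp_mm if t else nan
        out["Tb.N"] = t.tb_n_per_mm if t else nan
        m = self.mid_diaphysis
        out["Tt.Ar"] = m.tt_ar_mm2 if m else nan
        out["Ct.Ar"] = m.ct_ar_mm2 if m else nan
        out["Ct.Ar/Tt.Ar"] = m.ct_ar_tt_ar if m else nan
        out["Ct.Th"] = m.ct_th_mm if m else nan
        return out


def morphometry_report(volume: AttenuationVolume, labels: TissueLabelVolume,
                       seg: RegionSegmentation, profile: AxialProfile,
                       sample_id: str = "sample",
                       sc_mask: np.ndarray | None = None,
                       mid_diaphysis_window_um: float = 900.0,
                       distal_epiphysis_window_um: float = 990.0,
                       ct_th_mode: str = "slice") -> MorphometryReport:
    """Assemble the full report for one delimited sample.

    The trabecular block uses the cancellous compartment of the distal
    epiphysis, taken as the last ``distal_epiphysis_window_um`` of the
    bone (110 slices at 9 um).
    """
    if sc_mask is None:
        sc_mask, _ = endocortical_fill(labels)
    report = MorphometryReport(sample_id, whole_sample_metrics(volume, labels))
    region_names = ["whole", "prox_em", "diaphysis", "dist_em"]
    if seg.ab_split is not None:
        region_names += ["dia_A", "dia_B"]
    for region in region_names:
        report.regions[region] = regional_metrics(
            volume, labels, seg, profile, region, sc_mask=sc_mask)

    nz = labels.shape[0]
    n_dist = max(1, int(round(distal_epiphysis_window_um / labels.spacing[0])))
    dist_mask = np.zeros(labels.shape, dtype=bool)
    dist_mask[nz - n_dist:] = True
    if (labels.cancellous_mask & dist_mask).any():
        report.trabecular = trabecular_metrics(labels, dist_mask, sc_mask=sc_mask)
    try:
        report.mid_diaphysis = cortical_cross_section(
            labels, seg, profile, window_um=mid_diaphysis_window_um,
            mode=ct_th_mode)
    except ValueError:
        report.mid_diaphysis = None
    return report
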