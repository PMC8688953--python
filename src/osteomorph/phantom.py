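"""Synthetic long-bone phantoms with known ground truth.

The phantom emulates the specimen class the pipeline targets: a humerus-
scaled tube of dense cortical bone whose axial attenuation is flat along
the diaphysis and ramps (geometrically, so the per-section percent change
is constant and above the borderline threshold) through the proximal and
distal epiphysis+metaphysis zones; a rod-lattice of cancellous bone inside
the subcortical space of the EM-zones and of the distal half of the
diaphysis; flared outer radius toward the bone ends; optional additive
Gaussian noise.  Every generated voxel carries a generative tissue label,
and the planted region boundaries, lattice dimensions and analytic
cross-section values are returned as ground truth for testing.

Dimension targets (sample length ~15.9 mm, mid-shaft outer radius 626 um,
cortical thickness 344 um, trabecular rods ~72 um at ~330 um pitch,
boundaries at 18.5% / 15.6% of length) are humerus-scale values for an
adult Mongolian gerbil.  The default voxel is 18 um so that full-pipeline
runs stay desk-sized; geometry is specified in micrometres, so results are
spacing-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import AttenuationVolume, TissueLabelVolume, CORTICAL, CANCELLOUS

__all__ = ["PhantomSpec", "PhantomGroundTruth", "generate_phantom",
           "default_gerbil_spec"]


@dataclass
class PhantomSpec:
    """Generative description of a synthetic long bone."""

    length_mm: float = 15.9
    voxel_um: float = 18.0
    # planted region boundaries, as fractions of length from each end
    prox_boundary_frac: float = 0.185
    dist_boundary_frac: float = 0.156
    ab_split_frac: float = 0.60  # first distal-B coordinate, fraction of length
    # outer-radius profile (um): flared ends, narrow mid-shaft
    r_outer_prox_end_um: float = 1000.0
    r_outer_dia_edge_um: float = 820.0
    r_outer_mid_um: float = 626.0
    r_outer_dist_end_um: float = 950.0
    mid_plateau_half_um: float = 800.0
    # cortical thickness profile (um)
    ct_thick_mid_um: float = 344.0
    ct_thick_end_um: float = 200.0
    # cortical attenuation profile (mm^-1): plateau + geometric ramps
    mu_ct_dia: float = 1.304
    mu_ct_prox_end: float = 0.80
    mu_ct_dist_end: float = 0.85
    mu_trab: float = 0.85
    # trabecular rod lattice
    rod_thickness_um: float = 72.0
    rod_pitch_em_um: float = 330.0
    rod_pitch_b_um: float = 400.0
    noise_sd: float = 0.0
    seed: int = 0
    max_voxels: int = 80_000_000

    def __post_init__(self):
        if not (0 < self.prox_boundary_frac < 1 and 0 < self.dist_boundary_frac < 1):
            raise ValueError("boundary fractions must lie in (0, 1)")
        if self.prox_boundary_frac + self.dist_boundary_frac >= 1:
            raise ValueError("boundary fractions leave no diaphysis")
        if not (self.prox_boundary_frac < self.ab_split_frac
                < 1 - self.dist_boundary_frac):
            raise ValueError("ab_split_frac must lie inside the diaphysis")
        if self.ct_thick_mid_um >= self.r_outer_mid_um:
            raise ValueError("cortical thickness exceeds mid-shaft radius")
        for name, v in (("proximal", self.em_variation_per_100um("prox")),
                        ("distal", self.em_variation_per_100um("dist"))):
            if abs(v) <= 1.0:
                raise ValueError(
                    f"{name} EM attenuation ramp varies only {v:.2f}% per "
                    "100 um; must exceed the 1% borderline threshold")
        if self.n_voxels > self.max_voxels:
            raise ValueError(f"phantom would need {self.n_voxels} voxels "
                             f"(> cap {self.max_voxels})")

    @property
    def length_um(self) -> float:
        return self.length_mm * 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        nz = int(round(self.length_um / self.voxel_um))
        r_max = max(self.r_outer_prox_end_um, self.r_outer_dia_edge_um,
                    self.r_outer_mid_um, self.r_outer_dist_end_um)
        half = int(np.ceil(r_max / self.voxel_um)) + 4
        return nz, 2 * half, 2 * half

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def em_variation_per_100um(self, side: str) -> float:
        """Percent attenuation change per 100 um inside an EM ramp."""
        if side == "prox":
            span = self.prox_boundary_frac * self.length_um
            ratio = self.mu_ct_dia / self.mu_ct_prox_end
        else:
            span = self.dist_boundary_frac * self.length_um
            ratio = self.mu_ct_dist_end / self.mu_ct_dia
        return 100.0 * (ratio ** (100.0 / span) - 1.0)

    @property
    def cortical_contrast(self) -> float:
        """Cortical-to-background attenuation contrast (mm^-1)."""
        return self.mu_ct_dia


@dataclass
class PhantomGroundTruth:
    """Generative truth emitted alongside the phantom volume."""

    labels: TissueLabelVolume
    prox_boundary_um: float
    dist_boundary_um: float  # z of the distal borderline, from the proximal end
    ab_split_um: float
    prox_offset_pct: float
    dist_offset_pct: float
    region_ct_fraction: dict = field(default_factory=dict)
    region_cn_fraction: dict = field(default_factory=dict)
    tt_ar_mid_mm2: float = float("nan")
    ct_ar_mid_mm2: float = float("nan")
    ct_th_mid_mm: float = float("nan")
    rod_thickness_um: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "prox_boundary_um": self.prox_boundary_um,
            "dist_boundary_um": self.dist_boundary_um,
            "ab_split_um": self.ab_split_um,
            "prox_offset_pct": self.prox_offset_pct,
            "dist_offset_pct": self.dist_offset_pct,
            "region_ct_fraction": self.region_ct_fraction,
            "region_cn_fraction": self.region_cn_fraction,
            "tt_ar_mid_mm2": self.tt_ar_mid_mm2,
            "ct_ar_mid_mm2": self.ct_ar_mid_mm2,
            "ct_th_mid_mm": self.ct_th_mid_mm,
            "rod_thickness_um": self.rod_thickness_um,
        }


def _near_lattice(coords: np.ndarray, pitch: float, half_width: float) -> np.ndarray:
    """True where a coordinate lies within half_width of a lattice plane."""
    return np.abs(((coords + pitch / 2.0) % pitch) - pitch / 2.0) <= half_width


def _mu_ct_profile(spec: PhantomSpec, zc: np.ndarray) -> np.ndarray:
    zb1 = spec.prox_boundary_frac * spec.length_um
    zb2 = (1.0 - spec.dist_boundary_frac) * spec.length_um
    mu = np.full(zc.shape, spec.mu_ct_dia)
    prox = zc < zb1
    mu[prox] = spec.mu_ct_prox_end * (spec.mu_ct_dia / spec.mu_ct_prox_end) ** (
        zc[prox] / zb1)
    dist = zc > zb2
    mu[dist] = spec.mu_ct_dia * (spec.mu_ct_dist_end / spec.mu_ct_dia) ** (
        (zc[dist] - zb2) / (spec.length_um - zb2))
    return mu


def _radius_profiles(spec: PhantomSpec, zc: np.ndarray):
    L = spec.length_um
    zb1 = spec.prox_boundary_frac * L
    zb2 = (1.0 - spec.dist_boundary_frac) * L
    mid = (zb1 + zb2) / 2.0
    zpts = [0.0, zb1, mid - spec.mid_plateau_half_um,
            mid + spec.mid_plateau_half_um, zb2, L]
    # the proximal half of the diaphysis tapers from the EM flare to the
    # mid-shaft radius; the distal half stays cylindrical so the zone-B
    # cancellous fraction is flat, and the distal flare begins at the EM-zone
    rpts = [spec.r_outer_prox_end_um, spec.r_outer_dia_edge_um,
            spec.r_outer_mid_um, spec.r_outer_mid_um,
            spec.r_outer_mid_um, spec.r_outer_dist_end_um]
    r_outer = np.interp(zc, zpts, rpts)
    tpts = [spec.ct_thick_end_um, spec.ct_thick_mid_um, spec.ct_thick_mid_um,
            spec.ct_thick_mid_um, spec.ct_thick_mid_um, spec.ct_thick_end_um]
    thick = np.interp(zc, zpts, tpts)
    return r_outer, np.maximum(r_outer - thick, 0.0)


def generate_phantom(spec: PhantomSpec) -> tuple[AttenuationVolume, PhantomGroundTruth]:
    """Voxelize a phantom: deterministic for a fixed seed; surfaces use
    centre-in-surface inclusion; noise is added after labeling."""
    nz, ny, nx = spec.shape
    h = spec.voxel_um
    zc = (np.arange(nz) + 0.5) * h
    yc = (np.arange(ny) - (ny - 1) / 2.0) * h
    xc = (np.arange(nx) - (nx - 1) / 2.0) * h
    rr = np.hypot(yc[:, None], xc[None, :])

    r_outer, r_inner = _radius_profiles(spec, zc)
    mu_ct = _mu_ct_profile(spec, zc)

    L = spec.length_um
    zb1 = spec.prox_boundary_frac * L
    zb2 = (1.0 - spec.dist_boundary_frac) * L
    ab_z = spec.ab_split_frac * L

    half_rod = spec.rod_thickness_um / 2.0
    near_em = {
        "x": _near_lattice(xc, spec.rod_pitch_em_um, half_rod),
        "y": _near_lattice(yc, spec.rod_pitch_em_um, half_rod),
        "z": _near_lattice(zc, spec.rod_pitch_em_um, half_rod),
    }
    near_b = {
        "x": _near_lattice(xc, spec.rod_pitch_b_um, half_rod),
        "y": _near_lattice(yc, spec.rod_pitch_b_um, half_rod),
        "z": _near_lattice(zc, spec.rod_pitch_b_um, half_rod),
    }

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    mu = np.zeros((nz, ny, nx), dtype=np.float64)
    for k in range(nz):
        shell = (rr <= r_outer[k]) & (rr > r_inner[k])
        lumen = rr <= r_inner[k]
        z = zc[k]
        if z < zb1 or z >= zb2:
            # EM-zones: full 3D rod lattice (rods along all three axes)
            lat = near_em
            node_xy = lat["y"][:, None] & lat["x"][None, :]
            xr = lat["z"][k] & lat["y"]
            yr = lat["z"][k] & lat["x"]
            trab = lumen & (node_xy | xr[:, None] | yr[None, :])
        elif z >= ab_z:
            # distal diaphysis (zone B): sparse longitudinal rods only, so the
            # sectionwise cancellous fraction is low and smooth as in a shaft
            trab = lumen & (near_b["y"][:, None] & near_b["x"][None, :])
        else:
            trab = np.zeros_like(lumen)
        labels[k][shell] = CORTICAL
        labels[k][trab] = CANCELLOUS
        mu[k][shell] = mu_ct[k]
        mu[k][trab] = spec.mu_trab

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mu = mu + rng.normal(0.0, spec.noise_sd, size=mu.shape)

    spacing = (h, h, h)
    volume = AttenuationVolume(mu, spacing, allow_negative=spec.noise_sd > 0)
    label_vol = TissueLabelVolume(labels, spacing)

    # generative per-region fractions (mask counts, no image processing)
    ct_n = (labels == CORTICAL).sum(axis=(1, 2)).astype(np.int64)
    cn_n = (labels == CANCELLOUS).sum(axis=(1, 2)).astype(np.int64)
    tv_n = np.array([(rr <= r_outer[k]).sum() for k in range(nz)], dtype=np.int64)
    sc_n = np.array([(rr <= r_inner[k]).sum() for k in range(nz)], dtype=np.int64)
    ranges = {
        "whole": (0.0, L), "prox_em": (0.0, zb1), "diaphysis": (zb1, zb2),
        "dia_A": (zb1, ab_z), "dia_B": (ab_z, zb2), "dist_em": (zb2, L),
    }
    ct_frac, cn_frac = {}, {}
    for name, (a, b) in ranges.items():
        sel = (zc >= a) & (zc < b)
        tv, sc = tv_n[sel].sum(), sc_n[sel].sum()
        ct_frac[name] = float(ct_n[sel].sum() / tv) if tv else float("nan")
        cn_frac[name] = float(cn_n[sel].sum() / sc) if sc else float("nan")

    mid = (zb1 + zb2) / 2.0
    truth = PhantomGroundTruth(
        labels=label_vol,
        prox_boundary_um=zb1, dist_boundary_um=zb2, ab_split_um=ab_z,
        prox_offset_pct=100.0 * spec.prox_boundary_frac,
        dist_offset_pct=100.0 * spec.dist_boundary_frac,
        region_ct_fraction=ct_frac, region_cn_fraction=cn_frac,
        tt_ar_mid_mm2=np.pi * (spec.r_outer_mid_um / 1000.0) ** 2,
        ct_ar_mid_mm2=np.pi * ((spec.r_outer_mid_um / 1000.0) ** 2
                               - ((spec.r_outer_mid_um - spec.ct_thick_mid_um)
                                  / 1000.0) ** 2),
        ct_th_mid_mm=spec.ct_thick_mid_um / 1000.0,
        rod_thickness_um=spec.rod_thickness_um,
    )
    return volume, truth


def default_gerbil_spec(seed: int = 0, voxel_um: float = 18.0,
                        noise_sd: float = 0.0) -> PhantomSpec:
    """Humerus-scale phantom of an adult gerbil: 15.9 mm long, boundaries
    planted at 18.5% (proximal) and 15.6% (distal) of length."""
    return PhantomSpec(voxel_um=voxel_um, noise_sd=noise_sd, seed=seed)
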