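import numpy as np
import pytest

from osteomorph import (AttenuationVolume, TissueLabelVolume,
                        whole_sample_metrics, regional_metrics,
                        cortical_cross_section, morphometry_report)
from osteomorph.delimitation import RegionSegmentation
from osteomorph.morphometry import region_slice_range, _filled_slices
from osteomorph.segmentation import endocortical_fill
from conftest import hollow_cylinder_labels


def annulus_labels(nz, n, r_out_um, r_in_um, h_um):
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c) * h_um
    shell = (rr <= r_out_um) & (rr > r_in_um)
    labels = np.zeros((nz, n, n), dtype=np.uint8)
    labels[:, shell] = 1
    return TissueLabelVolume(labels, (h_um, h_um, h_um))


class TestWholeSample:
    def test_solid_cuboid_analytics(self):
        labels = np.ones((100, 10, 10), dtype=np.uint8)
        lv = TissueLabelVolume(labels, (9, 9, 9))
        vol = AttenuationVolume(np.full((100, 10, 10), 1.1), (9, 9, 9))
        w = whole_sample_metrics(vol, lv)
        assert w.sa_le_mm == pytest.approx(0.9)
        assert w.bv_mm3 == pytest.approx(w.tv_mm3)
        assert w.bv_tv == pytest.approx(1.0)

    def test_median_attenuation_of_three_levels(self):
        data = np.zeros((3, 1, 3))
        data[:, 0] = [[1, 2, 3]] * 3
        labels = TissueLabelVolume(np.ones((3, 1, 3), dtype=np.uint8), (9, 9, 9))
        w = whole_sample_metrics(AttenuationVolume(data, (9, 9, 9)), labels)
        assert w.mu_b == pytest.approx(2.0)

    def test_hollow_cylinder_tv_includes_marrow_cavity(self, hollow_cylinder):
        vol = AttenuationVolume(
            np.where(hollow_cylinder.bone_mask, 1.3, 0.0), hollow_cylinder.spacing)
        w = whole_sample_metrics(vol, hollow_cylinder)
        h = 9.0
        r_out, r_in, nz = 26 * h, 14 * h, 30
        tv_analytic = np.pi * r_out ** 2 * nz * h * 1e-9
        bvtv_analytic = 1 - (r_in / r_out) ** 2
        surf = 2 * np.pi * r_out / h * nz * hollow_cylinder.voxel_volume_um3 * 1e-9
        assert abs(w.tv_mm3 - tv_analytic) <= surf
        assert w.bv_tv == pytest.approx(bvtv_analytic, abs=0.03)

    def test_empty_labels_error(self):
        lv = TissueLabelVolume(np.zeros((3, 3, 3), dtype=np.uint8), (9, 9, 9))
        vol = AttenuationVolume(np.zeros((3, 3, 3)), (9, 9, 9))
        with pytest.raises(ValueError):
            whole_sample_metrics(vol, lv)


class TestRegional:
    def test_cortical_fraction_matches_generative_design(self):
        # annulus designed for a cortical area fraction of 0.69:
        # r_in/r_out = sqrt(1 - 0.69)
        h, r_out = 9.0, 500.0
        r_in = r_out * np.sqrt(1 - 0.69)
        labels = annulus_labels(20, 128, r_out, r_in, h)
        vol = AttenuationVolume(np.where(labels.bone_mask, 1.3, 0.0),
                                labels.spacing)
        from osteomorph import axial_profile
        prof = axial_profile(vol, labels, 100.0)
        seg = RegionSegmentation(0, prof.n_sections - 1)
        r = regional_metrics(vol, labels, seg, prof, "diaphysis")
        assert r.ct_bv_tv == pytest.approx(0.69, abs=0.02)

    def test_region_without_cancellous_has_zero_fraction(self, hollow_cylinder):
        vol = AttenuationVolume(
            np.where(hollow_cylinder.bone_mask, 1.3, 0.0), hollow_cylinder.spacing)
        from osteomorph import axial_profile
        prof = axial_profile(vol, hollow_cylinder, 100.0)
        seg = RegionSegmentation(0, prof.n_sections - 1)
        r = regional_metrics(vol, hollow_cylinder, seg, prof, "diaphysis")
        assert r.cn_bv_scv == 0.0
        assert r.sc_v_mm3 > 0

    def test_dia_a_plus_dia_b_reproduce_diaphysis_volumes(
            self, coarse_phantom, coarse_delimited):
        vol, truth = coarse_phantom
        seg, prof, _, sc = coarse_delimited
        labels = truth.labels
        nz = labels.shape[0]
        za = region_slice_range(seg, prof, "dia_A", nz)
        zb = region_slice_range(seg, prof, "dia_B", nz)
        zd = region_slice_range(seg, prof, "diaphysis", nz)
        assert za[0] == zd[0] and za[1] == zb[0] and zb[1] == zd[1]
        ct = labels.cortical_mask
        n_a = ct[za[0]:za[1]].sum()
        n_b = ct[zb[0]:zb[1]].sum()
        assert n_a + n_b == ct[zd[0]:zd[1]].sum()

    def test_phantom_regional_fractions_match_ground_truth(
            self, coarse_phantom, coarse_delimited):
        vol, truth = coarse_phantom
        seg, prof, _, sc = coarse_delimited
        for region in ("prox_em", "diaphysis", "dist_em"):
            r = regional_metrics(vol, truth.labels, seg, prof, region, sc_mask=sc)
            assert r.ct_bv_tv == pytest.approx(
                truth.region_ct_fraction[region], rel=0.02), region


class TestCorticalCrossSection:
    # annulus dimensions chosen to yield Tt.Ar ~1.23 mm^2, Ct.Ar ~0.98 mm^2,
    # Ct.Th ~0.344 mm (adult-gerbil humerus mid-shaft scale)
    R_OUT, R_IN, H = 626.0, 282.0, 9.0

    def annulus(self, nz=12, scale=1.0):
        r_out = self.R_OUT * scale
        n = 2 * int(np.ceil(r_out / self.H)) + 8
        return annulus_labels(nz, n, r_out, self.R_IN * scale, self.H)

    def test_analytic_annulus_areas_and_thickness(self):
        labels = self.annulus()
        m = cortical_cross_section(labels, slice_range=(0, 12))
        tt_analytic = np.pi * (self.R_OUT / 1000) ** 2
        ct_analytic = np.pi * ((self.R_OUT / 1000) ** 2 - (self.R_IN / 1000) ** 2)
        h_mm = self.H / 1000
        perim_bound = 2 * np.pi * self.R_OUT / 1000 * h_mm
        assert abs(m.tt_ar_mm2 - tt_analytic) <= perim_bound
        assert abs(m.ct_ar_mm2 - ct_analytic) <= 2 * perim_bound
        assert m.ct_th_mm == pytest.approx((self.R_OUT - self.R_IN) / 1000,
                                           abs=2 * h_mm)
        assert not m.degenerate

    def test_solid_disk_flagged_degenerate(self):
        labels = annulus_labels(6, 64, 200.0, -1.0, 9.0)
        m = cortical_cross_section(labels, slice_range=(0, 6))
        assert m.degenerate
        # without a lumen the medial surface collapses to the axis, where the
        # distance transform equals the disk radius: Ct.Th reports 2x radius
        assert m.ct_th_mm == pytest.approx(0.4, abs=0.05)

    def test_similarity_scaling(self):
        m1 = cortical_cross_section(self.annulus(), slice_range=(0, 12))
        m2 = cortical_cross_section(self.annulus(scale=2.0), slice_range=(0, 12))
        assert m2.tt_ar_mm2 == pytest.approx(4 * m1.tt_ar_mm2, rel=0.02)
        assert m2.ct_ar_mm2 == pytest.approx(4 * m1.ct_ar_mm2, rel=0.02)
        assert m2.ct_th_mm == pytest.approx(2 * m1.ct_th_mm, rel=0.05)

    def test_window_outside_diaphysis_errors(self, coarse_phantom, coarse_delimited):
        _, truth = coarse_phantom
        seg, prof, _, _ = coarse_delimited
        with pytest.raises(ValueError, match="window"):
            cortical_cross_section(truth.labels, seg, prof, window_um=50_000)


class TestUnitsScaling:
    def test_metric_quantities_scale_with_spacing_powers(self, coarse_phantom,
                                                         coarse_delimited):
        """mm, mm^2, mm^3 outputs scale as spacing^1, ^2, ^3 when the same
        voxel grid is declared at twice the voxel size."""
        vol, truth = coarse_phantom
        seg, prof, _, sc = coarse_delimited
        labels = truth.labels
        big = TissueLabelVolume(labels.labels, tuple(2 * s for s in labels.spacing))
        vol_big = AttenuationVolume(vol.data, big.spacing)
        w1 = whole_sample_metrics(vol, labels)
        w2 = whole_sample_metrics(vol_big, big)
        assert w2.sa_le_mm == pytest.approx(2 * w1.sa_le_mm)
        assert w2.tv_mm3 == pytest.approx(8 * w1.tv_mm3)
        assert w2.bv_tv == pytest.approx(w1.bv_tv)


def test_full_report_fields_consistent(coarse_phantom, coarse_delimited):
    vol, truth = coarse_phantom
    seg, prof, _, sc = coarse_delimited
    rep = morphometry_report(vol, truth.labels, seg, prof, sc_mask=sc)
    flat = rep.to_flat_dict()
    # volume partition: BV equals cortical+cancellous volume
    labels = truth.labels
    vox = labels.voxel_volume_um3 * 1e-9
    assert flat["BV"] == pytest.approx(
        (labels.cortical_mask.sum() + labels.cancellous_mask.sum()) * vox)
    assert 0 < flat["BV/TV"] <= 1
    assert flat["Ct.Ar"] <= flat["Tt.Ar"]
    assert rep.regions["dia_A"].cn_bv_scv < rep.regions["dia_B"].cn_bv_scv
    # mid-shaft values match the generative annulus
    assert flat["Tt.Ar"] == pytest.approx(truth.tt_ar_mid_mm2, rel=0.02)
    assert flat["Ct.Ar"] == pytest.approx(truth.ct_ar_mid_mm2, rel=0.02)
    assert abs(flat["Ct.Th"] - truth.ct_th_mid_mm) <= 1.5 * labels.spacing[0] / 1000
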