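import numpy as np
import pytest

from osteomorph import (AttenuationVolume, TissueLabelVolume, NoDiaphysisError,
                        axial_profile, variation_series, detect_boundaries,
                        boundary_offsets, subdivide_diaphysis,
                        split_em_zone_at_plate, delimit, generate_phantom,
                        default_gerbil_spec)
from osteomorph.delimitation import AxialProfile, RegionSegmentation, VariationSeries
from osteomorph.segmentation import endocortical_fill


def make_profile(mu, cn=None, section_um=100.0):
    mu = np.asarray(mu, dtype=float)
    n = len(mu)
    cn = np.zeros(n) if cn is None else np.asarray(cn, dtype=float)
    z = np.arange(n + 1) * section_um
    return AxialProfile(z[:-1], z[1:], mu, cn,
                        np.where(np.isfinite(mu), 100, 0), 1, section_um)


def tube_volume(mu_per_slice, nz_extra=0, n=32, spacing=9.0):
    """Shell-only tube whose cortical attenuation is constant per slice."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - c, xx - c)
    shell = (rr <= 12) & (rr > 7)
    nz = len(mu_per_slice)
    data = np.zeros((nz, n, n))
    labels = np.zeros((nz, n, n), dtype=np.uint8)
    for k, m in enumerate(mu_per_slice):
        data[k][shell] = m
        labels[k][shell] = 1
    sp = (spacing, spacing, spacing)
    return AttenuationVolume(data, sp), TissueLabelVolume(labels, sp)


class TestAxialProfile:
    def test_constant_cortical_attenuation_gives_constant_means(self):
        vol, labels = tube_volume([1.3] * 24)
        prof = axial_profile(vol, labels, section_thickness_um=100)
        assert np.allclose(prof.mean_ct_mu, 1.3)

    def test_section_grouping_is_ceil_of_thickness_over_spacing(self):
        vol, labels = tube_volume([1.0] * 30, spacing=9.0)
        prof = axial_profile(vol, labels, section_thickness_um=100)
        assert prof.slices_per_section == 12  # ceil(100/9)
        assert prof.n_sections == 3           # 12 + 12 + 6 (short last)
        assert prof.z_end_um[-1] == pytest.approx(30 * 9.0)

    def test_linear_ramp_section_means_hit_midpoints(self):
        nz, h = 48, 25.0
        mu = 1.0 + 0.002 * (np.arange(nz) + 0.5) * h  # linear in slice centre z
        vol, labels = tube_volume(mu, spacing=h)
        prof = axial_profile(vol, labels, section_thickness_um=100)
        # 4 slices per section; mean of a linear ramp = value at section middle
        mid = (prof.z_start_um + prof.z_end_um) / 2.0
        assert np.allclose(prof.mean_ct_mu, 1.0 + 0.002 * mid, rtol=1e-12)

    def test_no_cortical_voxels_errors(self):
        vol, labels = tube_volume([1.0] * 6)
        empty = TissueLabelVolume(np.zeros_like(labels.labels), labels.spacing)
        with pytest.raises(ValueError, match="cortical"):
            axial_profile(vol, empty)


class TestVariationSeries:
    def test_two_percent_step(self):
        v = variation_series(make_profile([1.00, 1.02]))
        assert v.values[1] == pytest.approx(2.0)

    def test_constant_profile_gives_zero_variation(self):
        v = variation_series(make_profile([1.1] * 5))
        assert np.allclose(v.values[1:], 0.0)

    def test_proximal_zone_attenuation_drop(self):
        # cortical means typical of a proximal EM-zone vs flight-group value
        v = variation_series(make_profile([0.943, 0.881]))
        assert v.values[1] == pytest.approx(100 * (0.881 - 0.943) / 0.943)
        assert v.values[1] == pytest.approx(-6.575, abs=5e-4)

    def test_scaling_all_means_leaves_variation_unchanged(self):
        mu = np.array([1.0, 1.05, 1.02, 0.99])
        v1 = variation_series(make_profile(mu)).values
        v2 = variation_series(make_profile(3.7 * mu)).values
        assert np.allclose(v1[1:], v2[1:])

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError, match="non-physical"):
            variation_series(make_profile([0.0, 1.0]))

    def test_undefined_sections_are_skipped(self):
        mu = [1.0, np.nan, 1.1, 1.1]
        v = variation_series(make_profile(mu))
        assert np.isnan(v.values[1])
        assert v.values[2] == pytest.approx(10.0)  # 1.0 -> 1.1 across the gap


def brute_force_central_run(values, thr, persistence):
    """Oracle: enumerate every contiguous quiet run, keep the longest."""
    quiet = [i for i in range(len(values))
             if np.isfinite(values[i]) and abs(values[i]) <= thr]
    runs, cur = [], []
    for i in quiet:
        if cur and i == cur[-1] + 1:
            cur.append(i)
        else:
            cur = [i]
            runs.append(cur)
    runs = [r for r in runs if len(r) >= persistence]
    if not runs:
        return None
    best = max(runs, key=len)
    return max(best[0] - 1, 0), best[-1]


class TestDetectBoundaries:
    def test_synthetic_series_matches_brute_force_scan(self):
        raw = [5, 3, 2, 0.5, 0.3, 0.2, 0.4, 2, 4]
        values = np.array([np.nan] + raw)
        got = detect_boundaries(VariationSeries(values), 1.0, 3)
        assert got == brute_force_central_run(values, 1.0, 3)
        # the four sub-threshold pairs cover sections 3..7
        assert got == (3, 7)

    def test_all_quiet_means_whole_bone_is_diaphysis(self):
        values = np.array([np.nan, 0.2, -0.3, 0.1, 0.4])
        assert detect_boundaries(VariationSeries(values)) == (0, 4)

    def test_no_sustained_run_raises_with_series_attached(self):
        values = np.array([np.nan, 5.0, -4.0, 3.0, 2.0])
        with pytest.raises(NoDiaphysisError) as err:
            detect_boundaries(VariationSeries(values))
        assert err.value.variation is not None

    def test_isolated_quiet_pair_does_not_trigger_boundary(self):
        values = np.array([np.nan, 5, 0.1, 4, 0.2, 0.1, 0.3, 0.2, 6])
        prox, dia = detect_boundaries(VariationSeries(values), 1.0, 3)
        assert (prox, dia) == (3, 7)

    def test_phantom_boundaries_recovered_over_noise_seeds(self, coarse_phantom):
        vol0, truth = coarse_phantom
        sc, _ = endocortical_fill(truth.labels)
        h = vol0.slice_spacing_um
        rng = np.random.default_rng(2024)
        sigma = 0.05 * 1.304  # 5% of cortical contrast
        hits = 0
        n_seeds = 20
        for _ in range(n_seeds):
            noisy = AttenuationVolume(
                vol0.data + rng.normal(0, sigma, vol0.shape), vol0.spacing,
                allow_negative=True)
            prof = axial_profile(noisy, truth.labels, 100.0, sc_mask=sc)
            prox, dia = detect_boundaries(variation_series(prof))
            sect_um = prof.slices_per_section * h
            if (abs(prof.z_start_um[prox] - truth.prox_boundary_um) <= sect_um
                    and abs(prof.z_end_um[dia] - truth.dist_boundary_um) <= sect_um):
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_flip_invariance_on_phantom(self, coarse_phantom):
        vol, truth = coarse_phantom
        seg_f, prof_f, _ = delimit(vol, truth.labels, subdivide=False)
        seg_r, prof_r, _ = delimit(vol.flipped(), truth.labels.flipped(),
                                   subdivide=False)
        n = prof_f.n_sections
        # flipped boundaries mirror the forward ones within one section
        assert abs((n - 1 - seg_r.dia_end) - seg_f.prox_em_end) <= 1
        assert abs((n - 1 - seg_r.prox_em_end) - seg_f.dia_end) <= 1


class TestOffsets:
    def test_direct_ratio(self):
        prof = make_profile([1.0] * 10, section_um=1590.0)  # 15.9 mm bone
        seg = RegionSegmentation(prox_em_end=1, dia_end=9)
        prox, dist = boundary_offsets(seg, prof)
        assert prox == pytest.approx(10.0)  # 1.59 mm of 15.9 mm
        assert dist == pytest.approx(0.0)

    def test_boundaries_at_both_ends_give_zero_offsets(self):
        prof = make_profile([1.0] * 8)
        seg = RegionSegmentation(prox_em_end=0, dia_end=7)
        assert boundary_offsets(seg, prof) == (0.0, 0.0)

    def test_nonpositive_length_errors(self):
        prof = make_profile([1.0] * 8)
        seg = RegionSegmentation(1, 6)
        with pytest.raises(ValueError):
            boundary_offsets(seg, prof, sample_length_um=0)

    def test_phantom_offsets_within_one_section(self, coarse_delimited,
                                                coarse_phantom):
        seg, profile, _, _ = coarse_delimited
        _, truth = coarse_phantom
        tol = 100.0 * profile.slices_per_section * profile.slice_spacing_um \
            / profile.length_um
        assert seg.prox_offset_pct == pytest.approx(truth.prox_offset_pct, abs=tol)
        assert seg.dist_offset_pct == pytest.approx(truth.dist_offset_pct, abs=tol)


def brute_force_split(series):
    """Oracle: exhaustive two-segment SSE over all split points."""
    best_k, best = None, np.inf
    for k in range(1, len(series)):
        a, b = series[:k], series[k:]
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if sse < best:
            best, best_k = sse, k
    return best_k


class TestSubdivideDiaphysis:
    def test_step_series_split_at_the_step(self):
        cn = np.array([0, 0, 0, 0, 3, 3, 3, 3]) / 100.0
        prof = make_profile(np.ones(8), cn)
        seg = RegionSegmentation(0, 7)
        out = subdivide_diaphysis(prof, seg)
        assert out.ab_split == 4

    def test_linear_series_matches_exhaustive_search(self):
        cn = np.linspace(0.0, 0.05, 9)
        prof = make_profile(np.ones(9), cn)
        out = subdivide_diaphysis(prof, RegionSegmentation(0, 8))
        assert out.ab_split == brute_force_split(cn)

    def test_constant_series_splits_at_midpoint_with_warning(self):
        prof = make_profile(np.ones(8), np.full(8, 0.02))
        with pytest.warns(UserWarning, match="midpoint"):
            out = subdivide_diaphysis(prof, RegionSegmentation(0, 7))
        assert out.ab_split == 4

    def test_em_boundaries_unchanged_by_subdivision(self, coarse_delimited):
        seg, profile, _, _ = coarse_delimited
        again = subdivide_diaphysis(profile, seg)
        assert (again.prox_em_end, again.dia_end) == (seg.prox_em_end, seg.dia_end)

    def test_phantom_ab_split_within_one_section(self, coarse_delimited,
                                                 coarse_phantom):
        seg, profile, _, _ = coarse_delimited
        _, truth = coarse_phantom
        sect_um = profile.slices_per_section * profile.slice_spacing_um
        assert abs(profile.z_start_um[seg.ab_split] - truth.ab_split_um) <= sect_um


class TestPlateSplit:
    def test_plate_at_inner_boundary_empties_metaphysis(self, coarse_delimited,
                                                        coarse_phantom):
        _, truth = coarse_phantom
        seg, profile, _, sc = coarse_delimited
        inner = profile.section_slice_bounds(seg.prox_em_end)[0]
        epi, meta = split_em_zone_at_plate(truth.labels, seg, profile, inner,
                                           zone="proximal", sc_mask=sc)
        assert not meta.any()
        assert epi.any()

    def test_union_covers_em_subcortical_exactly(self, coarse_delimited,
                                                 coarse_phantom):
        _, truth = coarse_phantom
        seg, profile, _, sc = coarse_delimited
        inner = profile.section_slice_bounds(seg.prox_em_end)[0]
        plate = inner // 2
        epi, meta = split_em_zone_at_plate(truth.labels, seg, profile, plate,
                                           zone="proximal", sc_mask=sc)
        assert not (epi & meta).any()
        expected = (sc | truth.labels.cancellous_mask).copy()
        expected[inner:] = False
        assert np.array_equal(epi | meta, expected)

    def test_plate_outside_zone_errors(self, coarse_delimited, coarse_phantom):
        _, truth = coarse_phantom
        seg, profile, _, sc = coarse_delimited
        with pytest.raises(ValueError, match="outside"):
            split_em_zone_at_plate(truth.labels, seg, profile,
                                   truth.labels.shape[0] - 1, zone="proximal",
                                   sc_mask=sc)
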