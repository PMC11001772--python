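"""Morphometric operations: profiles, ROIs, thickness, FFT, orientation."""

import numpy as np
import pytest
from scipy import ndimage

from sonomorph import morphometrics as mm
from sonomorph.exceptions import (
    BoundsError,
    ConfigError,
    DegenerateThresholdError,
    ResolutionError,
)

from oracles import brute_force_local_thickness, random_blob_mask


def make_profile(values, dr=1.0):
    values = np.asarray(values, dtype=float)
    radii = (np.arange(len(values)) + 0.5) * dr
    return mm.RadialProfile(radii=radii, values=values,
                            counts=np.ones(len(values), dtype=int), dr=dr,
                            center=(0.0, 0.0), pixel_pitch=dr)


class TestSegmentation:
    def test_two_level_image(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 100.0
        mask, info = mm.segment_foreground(img)
        assert np.array_equal(mask, img == 100.0)
        assert 0 < info["threshold"] < 100

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            mm.segment_foreground(np.full((16, 16), 7.0))

    def test_all_background_with_fixed_level(self):
        with pytest.warns(UserWarning, match="empty foreground"):
            mask, _ = mm.segment_foreground(np.zeros((16, 16)), "fixed", level=1.0)
        assert not mask.any()

    def test_recovers_generator_truth_fraction(self, ring_image):
        mask, _ = mm.segment_foreground(ring_image.intensity)
        truth_frac = ring_image.truth["cells_mask"].mean()
        assert mask.mean() == pytest.approx(truth_frac, rel=0.05)


class TestRadialProfile:
    def test_uniform_image_constant_profile(self):
        prof = mm.radial_profile(np.full((65, 65), 2.0), pixel_pitch=1.0)
        assert np.allclose(prof.values[prof.finite()], 2.0)

    def test_single_annulus_peaks_at_its_radius(self):
        n = 129
        rows = np.arange(n)[:, None] - 64
        cols = np.arange(n)[None, :] - 64
        r = np.hypot(rows, cols)
        img = ((r > 38) & (r < 42)).astype(float)
        prof = mm.radial_profile(img, pixel_pitch=1.0, dr=2.0)
        peak_r = prof.radii[np.nanargmax(prof.values)]
        assert abs(peak_r - 40.0) <= 2.0

    def test_mass_conservation(self, rng):
        img = rng.random((64, 64))
        prof = mm.radial_profile(img, pixel_pitch=1.0)
        total = np.nansum(np.where(prof.counts > 0, prof.values, 0.0)
                          * prof.counts)
        assert total == pytest.approx(img.sum(), rel=1e-12)

    def test_dr_below_pitch_rejected(self):
        with pytest.raises(ResolutionError):
            mm.radial_profile(np.ones((16, 16)), pixel_pitch=2.0, dr=1.0)

    def test_center_out_of_bounds(self):
        with pytest.raises(BoundsError):
            mm.radial_profile(np.ones((16, 16)), 1.0, center=(50.0, 2.0))


class TestPeaks:
    def test_monotone_profile_has_no_peaks(self):
        peaks = mm.detect_peaks(make_profile(np.linspace(0, 1, 50)))
        assert peaks.n_peaks == 0

    def test_triangle_wave_four_teeth(self):
        tooth = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        vals = np.concatenate([tooth] * 4)
        peaks = mm.detect_peaks(make_profile(vals))
        assert peaks.n_peaks == 4
        assert len(peaks.valley_positions) == 3

    def test_valley_to_peak_arithmetic(self):
        vals = np.array([0, 1, 0.2, 1, 0.2, 1, 0], dtype=float)
        peaks = mm.detect_peaks(make_profile(vals))
        assert mm.valley_to_peak_ratio(peaks) == pytest.approx(0.2)

    def test_zero_valleys_give_zero_ratio(self):
        vals = np.array([0, 1, 0, 1, 0, 1, 0], dtype=float)
        peaks = mm.detect_peaks(make_profile(vals))
        assert mm.valley_to_peak_ratio(peaks) == 0.0

    def test_single_peak_ratio_undefined(self):
        vals = np.array([0, 0, 1, 0, 0], dtype=float)
        peaks = mm.detect_peaks(make_profile(vals))
        with pytest.warns(UserWarning):
            assert np.isnan(mm.valley_to_peak_ratio(peaks))

    def test_interring_fill_increases_ratio(self):
        """As the inter-ring space fills in (capillary growth between
        rings), the valley-to-peak ratio increases strictly."""
        ratios = []
        for fill in (0.0, 0.2, 0.4, 0.6):
            vals = np.array([0, 1, fill, 1, fill, 1, 0], dtype=float)
            peaks = mm.detect_peaks(make_profile(vals))
            ratios.append(mm.valley_to_peak_ratio(peaks))
        assert np.all(np.diff(ratios) > 0)


class TestFWHM:
    def test_rectangular_peak(self):
        vals = np.zeros(60)
        vals[20:31] = 1.0  # 11 samples wide
        peaks = mm.detect_peaks(make_profile(vals))
        w = mm.ring_fwhm(make_profile(vals), peaks, 0)
        assert w == pytest.approx(11.0, abs=1.0)

    def test_gaussian_peak_closed_form(self):
        r = np.arange(100) + 0.5
        sigma = 5.0
        vals = np.exp(-((r - 50) ** 2) / (2 * sigma ** 2))
        prof = make_profile(vals)
        peaks = mm.detect_peaks(prof)
        w = mm.ring_fwhm(prof, peaks, 0)
        assert w == pytest.approx(2.3548 * sigma, rel=0.05)

    def test_censored_width_signal(self):
        vals = np.linspace(0.8, 1.0, 20)  # rises to an edge peak, never drops
        vals[-1] = 1.0
        prof = make_profile(vals)
        peaks = mm.PeakSet(
            peak_positions=np.array([prof.radii[-1]]),
            peak_heights=np.array([1.0]),
            valley_positions=np.array([]), valley_depths=np.array([]),
            peak_indices=np.array([len(vals) - 1]),
            valley_indices=np.array([], dtype=int), prominence=0.1)
        with pytest.warns(UserWarning, match="censored"):
            assert np.isnan(mm.ring_fwhm(prof, peaks, 0))

    def test_programmed_100um_ring_within_printed_band(self, ring_image):
        prof = mm.radial_profile(ring_image.intensity.astype(float),
                                 ring_image.pixel_pitch,
                                 dr=2 * ring_image.pixel_pitch,
                                 r_max=2400.0)
        peaks = mm.detect_peaks(prof, prominence=0.25)
        truth_r = ring_image.truth["ring_radii_um"][0]
        which = int(np.argmin(np.abs(peaks.peak_positions - truth_r)))
        w = mm.ring_fwhm(prof, peaks, which)
        assert 80.0 <= w <= 120.0


def _triplet(location, centers, side_um):
    return [mm.ROI(location, c, side_um) for c in centers]


class TestROIEnhancement:
    def test_deterministic_fixture_400_percent(self):
        mask = np.zeros((100, 100), dtype=bool)
        control = np.zeros((100, 100), dtype=bool)
        centers = [(20.0, 20.0), (20.0, 50.0), (20.0, 80.0)]
        for _, c in enumerate(centers):
            r0, c0 = int(c[0] - 5), int(c[1] - 5)
            mask[r0:r0 + 5, c0:c0 + 10] = True      # half the ROI -> 0.5
            control[r0:r0 + 1, c0:c0 + 10] = True   # a tenth -> 0.1
        layout = mm.ROILayout(_triplet("on_pattern", centers, 10.0)
                              + _triplet("random", centers, 10.0),
                              pixel_pitch=1.0)
        res = mm.roi_density_enhancement(mask, layout, control)
        assert res.enhancement_pct == pytest.approx(400.0)

    def test_identical_masks_zero_enhancement(self, rng):
        mask = rng.random((100, 100)) > 0.7
        centers = [(30.0, 30.0), (30.0, 60.0), (60.0, 45.0)]
        layout = mm.ROILayout(_triplet("on_pattern", centers, 10.0)
                              + _triplet("random", centers, 10.0),
                              pixel_pitch=1.0)
        res = mm.roi_density_enhancement(mask, layout, mask)
        assert res.enhancement_pct == pytest.approx(0.0, abs=1e-12)

    def test_zero_control_undefined(self):
        mask = np.ones((100, 100), dtype=bool)
        centers = [(30.0, 30.0), (30.0, 60.0), (60.0, 45.0)]
        layout = mm.ROILayout(_triplet("on_pattern", centers, 10.0)
                              + _triplet("random", centers, 10.0),
                              pixel_pitch=1.0)
        with pytest.warns(UserWarning, match="undefined"):
            res = mm.roi_density_enhancement(mask, layout,
                                             np.zeros((100, 100), dtype=bool))
        assert np.isnan(res.enhancement_pct)

    def test_layout_requires_three_rois(self):
        with pytest.raises(ConfigError):
            mm.ROILayout(_triplet("on_pattern",
                                  [(10.0, 10.0), (20.0, 20.0)], 10.0)[:2],
                         pixel_pitch=1.0)

    def test_roi_outside_image_rejected(self):
        centers = [(2.0, 2.0), (30.0, 60.0), (60.0, 45.0)]
        layout = mm.ROILayout(_triplet("on_pattern", centers, 10.0)
                              + _triplet("random", centers, 10.0),
                              pixel_pitch=1.0)
        with pytest.raises(BoundsError):
            mm.roi_density_enhancement(np.ones((100, 100), dtype=bool), layout,
                                       np.ones((100, 100), dtype=bool))


class TestLocalThickness:
    def test_filled_disc_equals_diameter(self):
        n = 64
        r = np.hypot(np.arange(n)[:, None] - 32, np.arange(n)[None, :] - 32)
        mask = r < 20.0
        tmap = mm.local_thickness(mask, pixel_pitch=1.0)
        vals = tmap.values[mask]
        assert np.all(np.abs(vals - 40.0) <= 1.0)

    def test_straight_ribbon_equals_width(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:150, :] = True
        tmap = mm.local_thickness(mask, pixel_pitch=1.0)
        assert np.all(np.abs(tmap.values[mask] - 100.0) <= 1.0)

    def test_zero_iff_background(self, rng):
        mask = random_blob_mask(5)
        tmap = mm.local_thickness(mask)
        assert np.all((tmap.values > 0) == mask)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        mask = random_blob_mask(seed)
        tmap = mm.local_thickness(mask, pixel_pitch=1.0)
        assert np.allclose(tmap.values, brute_force_local_thickness(mask))

    def test_empty_mask_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            tmap = mm.local_thickness(np.zeros((16, 16), dtype=bool))
        assert not tmap.values.any()


class TestThicknessStats:
    def test_uniform_ribbon(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:150, :] = True
        tmap = mm.local_thickness(mask, pixel_pitch=1.0)
        st = mm.thickness_stats(tmap)
        assert st.mean == pytest.approx(100.0, abs=1.0)
        assert st.sd < 10.0

    def test_equal_area_ribbons_average(self):
        # three 50 px ribbons + one 150 px ribbon: equal total areas
        mask = np.zeros((400, 400), dtype=bool)
        for r0 in (10, 70, 130):
            mask[r0:r0 + 50, :] = True
        mask[200:350, :] = True
        tmap = mm.local_thickness(mask, pixel_pitch=1.0)
        st = mm.thickness_stats(tmap)
        assert st.mean == pytest.approx(100.0, abs=1.5)

    def test_include_zero_convention(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:50, :] = True
        tmap = mm.local_thickness(mask, pixel_pitch=1.0)
        fg = mm.thickness_stats(tmap, include_zero=False)
        allpx = mm.thickness_stats(tmap, include_zero=True)
        assert allpx.mean == pytest.approx(fg.mean * 0.5, rel=0.03)
        assert allpx.n_pixels == 10000 and fg.n_pixels == 5000

    def test_day5_network_recovery(self):
        """Thickness-map mean recovers the realized (area-weighted) ribbon
        width of the day-5 preset within 20%."""
        from sonomorph import synth
        ratios = []
        for seed in (3, 4, 5):
            net = synth.generate_network_image(
                synth.NetworkSpec(day=5, ribbon_count=6, image_size=512,
                                  pixel_pitch=0.5, seed=seed))
            tmap = mm.local_thickness(net.cells_mask, 0.5)
            st = mm.thickness_stats(tmap)
            num = den = 0.0
            for r in net.truth["ribbons"]:
                length = np.sum(np.hypot(
                    *np.diff(r["centerline_px"], axis=0).T))
                num += r["width_um"] ** 2 * length
                den += r["width_um"] * length
            ratios.append(st.mean / (num / den))
        assert np.all(np.abs(np.array(ratios) - 1.0) < 0.2)


class TestFFTHighpass:
    def test_constant_image_zeroed(self):
        out = mm.fft_highpass(np.full((64, 64), 5.0), cutoff=10)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_high_frequency_preserved(self):
        x = np.arange(128)
        img = np.sin(2 * np.pi * 20 * x / 128)[None, :] * np.ones((128, 1))
        out = mm.fft_highpass(img, cutoff=10)
        corr = np.corrcoef(img.ravel(), out.ravel())[0, 1]
        assert corr > 0.99

    def test_low_frequency_suppressed(self):
        x = np.arange(128)
        img = np.sin(2 * np.pi * 4 * x / 128)[None, :] * np.ones((128, 1))
        out = mm.fft_highpass(img, cutoff=10)
        assert (out ** 2).sum() < 0.01 * (img ** 2).sum()

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            mm.fft_highpass(np.ones((64, 64)), cutoff=40)


def _stripes(angle_deg=0.0, n=256, period=16):
    y = np.arange(n)[:, None] * np.ones((1, n))
    img = np.sin(2 * np.pi * y / period)
    if angle_deg:
        img = ndimage.rotate(img, angle_deg, reshape=False, order=3)
        img = img[n // 4: 3 * n // 4, n // 4: 3 * n // 4]
    return img


class TestOrientation:
    def test_horizontal_stripes_concentrated_at_zero(self):
        h = mm.orientation_distribution(_stripes())
        near_zero = np.abs(h.bin_centers) <= 3.0
        assert h.weights[near_zero].sum() > 0.9
        assert h.weights.sum() == pytest.approx(1.0)

    def test_rotation_equivariance(self):
        h0 = mm.orientation_distribution(_stripes()[64:192, 64:192])
        h45 = mm.orientation_distribution(_stripes(45.0))
        d0 = h0.bin_centers[np.argmax(h0.weights)]
        d45 = h45.bin_centers[np.argmax(h45.weights)]
        assert abs((d45 - d0) - 45.0) <= 1.0

    def test_reflection_negates_angles(self):
        img = _stripes(30.0)
        h = mm.orientation_distribution(img)
        hr = mm.orientation_distribution(np.flipud(img))
        d = h.bin_centers[np.argmax(h.weights)]
        dr = hr.bin_centers[np.argmax(hr.weights)]
        assert abs(d + dr) <= 3.0  # smoothing-plateau tolerance

    def test_isotropic_noise_is_flat(self, rng):
        h = mm.orientation_distribution(rng.normal(size=(256, 256)))
        assert h.weights.max() < 3.0 / len(h.weights)

    def test_all_below_threshold_is_empty_signal(self):
        with pytest.warns(UserWarning):
            h = mm.orientation_distribution(np.zeros((64, 64)))
        assert h.empty
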