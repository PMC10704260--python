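"""ROI analyses: smoothing, angular histograms, path profiles, rotation series."""

import numpy as np
import pytest
from scipy import ndimage

import plimap as pl
from plimap import (
    EmptyROIError,
    InsufficientDataError,
    InvalidArgumentError,
    OutOfBoundsError,
)


def _maps(ret, angle=None, validity=None, wavelength=532.0):
    ret = np.asarray(ret, float)
    angle = np.full(ret.shape, np.nan) if angle is None else np.asarray(angle, float)
    validity = np.ones(ret.shape, bool) if validity is None else validity
    zero = np.zeros(ret.shape)
    return pl.PolarizationMaps(ret, angle, zero.copy(), angle.copy(), zero.copy(),
                               wavelength, validity)


class TestSmoothMaps:
    def test_constant_map_unchanged(self):
        maps = _maps(np.full((20, 20), 1.7))
        out = pl.smooth_maps(maps, sigma=3.0)
        np.testing.assert_allclose(out.retardance, 1.7, atol=1e-12)

    def test_sigma_zero_is_identity(self):
        maps = _maps(np.random.default_rng(0).random((10, 10)))
        out = pl.smooth_maps(maps, sigma=0.0)
        np.testing.assert_array_equal(out.retardance, maps.retardance)

    def test_impulse_gives_gaussian_kernel(self):
        """A unit impulse smooths to the discrete Gaussian kernel values."""
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = pl.smooth_maps(_maps(img), sigma=2.0)
        expect = ndimage.gaussian_filter(img, 2.0, mode="reflect")
        np.testing.assert_allclose(out.retardance, expect, atol=1e-12)

    def test_mean_preserved_over_fully_valid_frame(self):
        rng = np.random.default_rng(7)
        img = rng.random((30, 30))
        out = pl.smooth_maps(_maps(img), sigma=10.0)
        assert np.mean(out.retardance) == pytest.approx(np.mean(img), abs=1e-6)

    def test_invalid_pixels_excluded_and_stay_invalid(self):
        img = np.ones((15, 15))
        img[7, 7] = 100.0  # would leak if counted
        validity = np.ones((15, 15), bool)
        validity[7, 7] = False
        maps = _maps(np.where(validity, img, np.nan), validity=validity)
        out = pl.smooth_maps(maps, sigma=2.0)
        assert np.isnan(out.retardance[7, 7])
        np.testing.assert_allclose(out.retardance[validity], 1.0, atol=1e-9)

    def test_angle_smoothing_respects_axial_period(self):
        """Angles straddling the 0/180 wrap average near the wrap, not at 90."""
        angle = np.where(np.arange(400).reshape(20, 20) % 2 == 0, 175.0, 5.0)
        out = pl.smooth_maps(_maps(np.ones((20, 20)), angle=angle), sigma=3.0)
        interior = out.retardance_angle[5:15, 5:15]
        dist = np.abs(pl.axial_difference(interior, 0.0))
        assert np.nanmax(dist) < 10.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pl.smooth_maps(_maps(np.ones((5, 5))), sigma=-1.0)


class TestAngularDistribution:
    def test_single_angle_single_bin(self):
        angle = np.full((10, 10), 45.0)
        hist = pl.angular_distribution(angle, pl.ROIMask(np.ones((10, 10), bool)))
        assert hist.dominant_angle == pytest.approx(47.5)  # center of the [45,50) bin
        assert hist.heights.max() == 1.0
        assert np.count_nonzero(hist.heights) == 1
        assert hist.n_pixels == 100

    def test_tie_resolved_by_axial_mean(self):
        angle = np.where(np.arange(100).reshape(10, 10) < 50, 30.0, 120.0)
        hist = pl.angular_distribution(angle, pl.ROIMask(np.ones((10, 10), bool)))
        assert np.count_nonzero(hist.heights == 1.0) == 2
        assert hist.dominant_angle == pytest.approx(pl.axial_mean([32.5, 122.5]))

    def test_rotation_equivariance_within_bin_resolution(self):
        rng = np.random.default_rng(3)
        angle = rng.normal(40.0, 3.0, (30, 30)) % 180.0
        mask = pl.ROIMask(np.ones((30, 30), bool))
        base = pl.angular_distribution(angle, mask)
        shifted = pl.angular_distribution((angle + 65.0) % 180.0, mask)
        diff = abs(float(pl.axial_difference(shifted.dominant_angle,
                                             base.dominant_angle + 65.0)))
        assert diff <= 5.0  # one bin

    def test_weights_change_the_mode(self):
        angle = np.where(np.arange(100).reshape(10, 10) < 40, 30.0, 120.0)
        weights = np.where(angle == 30.0, 10.0, 1.0)
        hist = pl.angular_distribution(angle, pl.ROIMask(np.ones((10, 10), bool)),
                                       weights_map=weights)
        assert hist.dominant_angle == pytest.approx(32.5)

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyROIError):
            pl.angular_distribution(np.full((5, 5), 10.0),
                                    pl.ROIMask(np.zeros((5, 5), bool)))

    def test_too_few_bins_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pl.angular_distribution(np.full((5, 5), 10.0),
                                    pl.ROIMask(np.ones((5, 5), bool)), n_bins=2)


class TestPathProfile:
    def test_constant_map_constant_profile(self):
        prof = pl.profile_along_path(np.full((20, 40), 2.0), [[3, 10], [36, 10]],
                                     transverse_width=4.0)
        np.testing.assert_allclose(prof.values, 2.0, atol=1e-12)

    def test_linear_map_linear_profile_with_matching_slope(self):
        x = np.arange(64, dtype=float)[None, :].repeat(32, 0)
        prof = pl.profile_along_path(0.5 * x, [[5, 16], [58, 16]],
                                     transverse_width=6.0, pixel_pitch=2.0)
        fit = pl.linear_fit_profile(prof)
        assert fit.slope == pytest.approx(0.25, abs=1e-9)  # 0.5 per px / 2 um per px
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_stations_in_micrometres(self):
        prof = pl.profile_along_path(np.ones((10, 30)), [[2, 5], [27, 5]],
                                     transverse_width=2.0, pixel_pitch=10.0)
        assert prof.stations[1] - prof.stations[0] == pytest.approx(10.0)

    def test_single_vertex_path_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pl.profile_along_path(np.ones((10, 10)), [[5, 5]], transverse_width=2.0)

    def test_path_outside_image_rejected(self):
        with pytest.raises(OutOfBoundsError):
            pl.profile_along_path(np.ones((10, 10)), [[0, 0], [50, 0]],
                                  transverse_width=2.0)

    def test_all_invalid_station_gets_sentinel(self):
        img = np.ones((10, 30))
        img[:, 15] = np.nan
        prof = pl.profile_along_path(img, [[2, 5], [27, 5]], transverse_width=0.5)
        assert np.isnan(prof.values[13])
        assert np.isfinite(prof.values[5])


class TestLinearFitProfile:
    def test_exact_line_recovered(self):
        prof = pl.PathProfile(np.arange(10.0), 3.0 * np.arange(10.0) + 1.0, 2.0)
        fit = pl.linear_fit_profile(prof)
        assert fit.slope == pytest.approx(3.0) and fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_values_zero_slope(self):
        prof = pl.PathProfile(np.arange(10.0), np.full(10, 4.0), 2.0)
        assert pl.linear_fit_profile(prof).slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_slope_within_three_stderr(self, rng):
        x = np.arange(200.0)
        noise_sd = 0.3
        y = 0.05 * x + 2.0 + rng.normal(0, noise_sd, x.size)
        fit = pl.linear_fit_profile(pl.PathProfile(x, y, 2.0))
        # analytic OLS standard error of the slope
        se = noise_sd / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.slope - 0.05) < 3 * se

    def test_insufficient_stations_rejected(self):
        with pytest.raises(InsufficientDataError):
            pl.linear_fit_profile(pl.PathProfile(np.array([1.0]), np.array([2.0]), 1.0))


class TestRegisterRotation:
    def test_zero_stage_angle_is_identity(self):
        maps = _maps(np.random.default_rng(1).random((12, 12)))
        out = pl.register_rotation(maps, 0.0)
        np.testing.assert_array_equal(out.retardance, maps.retardance)

    def test_ninety_degree_rotation_matches_rot90_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.random((16, 16))
        out = pl.register_rotation(_maps(img), 90.0)
        expect = np.rot90(img, 1)
        ok = np.isfinite(out.retardance)
        assert ok.sum() > 200
        np.testing.assert_allclose(out.retardance[ok], expect[ok], atol=1e-9)

    def test_angle_values_shift_by_minus_stage_angle(self):
        angle = np.full((16, 16), 30.0)
        out = pl.register_rotation(_maps(np.ones((16, 16)), angle=angle), 40.0)
        interior = out.retardance_angle[5:11, 5:11]
        np.testing.assert_allclose(interior, 170.0, atol=1e-6)

    def test_out_of_frame_marked_invalid(self):
        maps = _maps(np.ones((16, 16)))
        out = pl.register_rotation(maps, 45.0)
        assert not out.validity[0, 0]  # corner leaves the frame under rotation


class TestRotationSeries:
    def _noise_free_series(self, inclination=30.0, n_wl=1):
        scenes = pl.preset_phantom(
            "rotation_series", wavelengths=(532.0,), size=(64, 64),
            inclination=inclination,
        )
        phis, rets, angs = [], [], []
        for phi, scene in scenes:
            stack, truth = pl.scene_to_mueller(scene)
            maps = pl.decompose_stack(stack)[0]
            sel = (truth.fiber_id >= 0) & maps.validity
            phis.append(phi)
            rets.append(float(np.mean(maps.retardance[sel])))
            angs.append(pl.axial_mean(maps.retardance_angle[sel]))
        return pl.RotationSeries(np.array(phis), {"roi": np.array(rets)},
                                 {"roi": np.array(angs)})

    def test_angle_slope_is_unity_noise_free(self):
        fits = pl.rotation_series_analysis(self._noise_free_series())
        assert fits["roi"].angle_slope == pytest.approx(1.0, abs=0.01)

    def test_constant_retardance_gives_near_zero_amplitude(self):
        series = self._noise_free_series()
        fits = pl.rotation_series_analysis(series)
        assert fits["roi"].amplitude == pytest.approx(0.0, abs=1e-6)

    def test_two_orientations_line_only(self):
        series = pl.RotationSeries(np.array([0.0, 30.0]),
                                   {"roi": np.array([1.0, 1.0])},
                                   {"roi": np.array([10.0, 40.0])})
        fits = pl.rotation_series_analysis(series)
        assert fits["roi"].amplitude is None
        assert fits["roi"].angle_slope == pytest.approx(1.0)

    def test_duplicate_orientations_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pl.RotationSeries(np.array([0.0, 0.0]), {}, {})


class TestAxialStatistics:
    def test_axial_mean_straddles_wrap(self):
        mean = pl.axial_mean([175.0, 5.0])
        assert abs(float(pl.axial_difference(mean, 0.0))) == pytest.approx(0.0, abs=1e-9)

    def test_axial_mean_of_opposed_pair(self):
        assert pl.axial_mean([30.0, 150.0]) == pytest.approx(0.0, abs=1e-9)

    def test_axial_difference_range(self):
        assert float(pl.axial_difference(170.0, 10.0)) == pytest.approx(-20.0)
        assert float(pl.axial_difference(10.0, 170.0)) == pytest.approx(20.0)
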