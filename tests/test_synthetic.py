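import numpy as np
import pytest

from ddmqa import (
    DosePlane,
    ErrorSpec,
    SpotField,
    apply_error,
    dome_plane,
    downsample_to_detector,
    grid_spot_field,
    make_pair,
    render_plane,
    sample_radial_deviations,
    summarize_deviations,
    uniform_plane,
)
from ddmqa.synthetic import folded_normal_params


class TestRender:
    def test_single_spot_peaks_at_center(self):
        field = SpotField(spots=[[2.0, -3.0, 10.0, 4.0]],
                          extent_mm=((-20, 20), (-20, 20)))
        plane = render_plane(field, spacing_mm=1.0)
        i, j = np.unravel_index(np.argmax(plane.values), plane.shape)
        rr, cc = plane.pixel_positions()
        assert (rr[i, j], cc[i, j]) == (2.0, -3.0)
        assert plane.values[i, j] == pytest.approx(10.0)

    def test_two_equal_spots_symmetric_maxima(self):
        field = SpotField(spots=[[0, -12, 5, 3], [0, 12, 5, 3]],
                          extent_mm=((-25, 25), (-25, 25)))
        plane = render_plane(field, spacing_mm=0.5)
        np.testing.assert_allclose(plane.values, plane.values[:, ::-1],
                                   atol=1e-12)
        assert np.count_nonzero(
            np.isclose(plane.values, plane.values.max())) == 2

    def test_total_integral_matches_analytic(self):
        # each unit-peak Gaussian integrates to w * 2 * pi * sigma^2
        field = grid_spot_field(half_size_mm=10.0, pitch_mm=5.0, sigma_mm=3.0,
                                margin_mm=25.0)
        plane = render_plane(field, spacing_mm=0.5)
        integral = plane.values.sum() * plane.spacing[0] * plane.spacing[1]
        expected = field.spots[:, 2].sum() * 2 * np.pi * 3.0**2
        assert integral == pytest.approx(expected, rel=1e-4)

    def test_empty_spot_list_rejected(self):
        with pytest.raises(ValueError):
            SpotField(spots=np.empty((0, 4)), extent_mm=((0, 1), (0, 1)))


class TestApplyError:
    def test_zero_magnitude_is_identity(self):
        plane = uniform_plane(size_mm=20.0, spacing_mm=1.0)
        for kind in ("global_scale", "noise"):
            out = apply_error(plane, ErrorSpec(kind=kind, magnitude_pct=0.0))
            np.testing.assert_array_equal(out.values, plane.values)

    def test_region_offset_scales_exactly(self):
        plane = uniform_plane(size_mm=40.0, dose=100.0, spacing_mm=2.0)
        spec = ErrorSpec(kind="region_offset", magnitude_pct=5.0,
                         region=((-10, 10), (-10, 10)))
        out = apply_error(plane, spec)
        rr, cc = plane.pixel_positions()
        inside = (np.abs(rr) <= 10) & (np.abs(cc) <= 10)
        np.testing.assert_allclose(out.values[inside], 105.0)
        np.testing.assert_allclose(out.values[~inside], 100.0)

    def test_region_outside_plane_rejected(self):
        plane = uniform_plane(size_mm=20.0)
        spec = ErrorSpec(kind="region_offset", magnitude_pct=5.0,
                         region=((-50, 50), (-50, 50)))
        with pytest.raises(ValueError):
            apply_error(plane, spec)

    def test_spot_jitter_displacement_sd(self):
        from ddmqa.synthetic import jitter_spots

        field = grid_spot_field(half_size_mm=78.0, pitch_mm=5.0, sigma_mm=5.0)
        assert len(field.spots) >= 1000
        moved = jitter_spots(field, 0.19, np.random.default_rng(3))
        disp = moved.spots[:, :2] - field.spots[:, :2]
        assert disp.std() == pytest.approx(0.19, rel=0.10)
        # weights and sigmas untouched
        np.testing.assert_array_equal(moved.spots[:, 2:], field.spots[:, 2:])

    def test_spot_jitter_requires_field(self):
        plane = uniform_plane(size_mm=20.0)
        with pytest.raises(ValueError):
            apply_error(plane, ErrorSpec(kind="spot_jitter", jitter_mm=0.1))

    def test_noise_deterministic_at_seed(self):
        plane = uniform_plane(size_mm=20.0)
        spec = ErrorSpec(kind="noise", magnitude_pct=2.0, seed=9)
        a = apply_error(plane, spec)
        b = apply_error(plane, spec)
        np.testing.assert_array_equal(a.values, b.values)


class TestDetector:
    def test_constant_plane_sampled_constant(self):
        plane = uniform_plane(size_mm=60.0, dose=80.0)
        det = downsample_to_detector(plane)
        np.testing.assert_allclose(det.values, 80.0)

    def test_detector_pitch_is_7_62(self):
        det = downsample_to_detector(uniform_plane(size_mm=100.0))
        assert det.spacing == (7.62, 7.62)
        coords = det.axis_coords(0)
        np.testing.assert_allclose(np.diff(coords), 7.62)
        assert 0.0 in coords  # centered on isocenter

    def test_point_samples_equal_interpolated_truth(self):
        rng = np.random.default_rng(5)
        plane = DosePlane(rng.uniform(0, 100, (61, 61)), spacing=(1.0, 1.0),
                          origin=(-30.0, -30.0))
        det = downsample_to_detector(plane, pitch_mm=7.62)
        interp = plane.interpolator()
        rr, cc = det.pixel_positions()
        truth = interp(np.stack([rr.ravel(), cc.ravel()], 1)).reshape(det.shape)
        np.testing.assert_allclose(det.values, truth)

    def test_pitch_finer_than_grid_rejected(self):
        with pytest.raises(ValueError):
            downsample_to_detector(uniform_plane(spacing_mm=2.0), pitch_mm=1.0)


class TestDeviationSampling:
    def test_moments_recovered_at_scale(self):
        dev = sample_radial_deviations(10**4, 0.38, 0.19, seed=0)
        s = summarize_deviations(dev, limit_mm=1.0)
        assert s.mean_mm == pytest.approx(0.38, abs=0.01)
        assert s.sd_mm == pytest.approx(0.19, abs=0.01)
        # clinical spot accuracy: ~99.9% of spots within 1 mm
        assert s.frac_below_limit == pytest.approx(0.999, abs=0.002)

    def test_regeneration_bit_identical(self):
        a = sample_radial_deviations(500, 0.38, 0.19, seed=7)
        b = sample_radial_deviations(500, 0.38, 0.19, seed=7)
        np.testing.assert_array_equal(a.radial_deviation_mm,
                                      b.radial_deviation_mm)

    def test_vanishing_sd_concentrates_at_mean(self):
        dev = sample_radial_deviations(50, 0.4, 0.0, seed=0)
        np.testing.assert_allclose(dev.radial_deviation_mm, 0.4)

    def test_folded_normal_moment_matching(self):
        mu, sigma = folded_normal_params(0.38, 0.19)
        from ddmqa.synthetic import _folded_moments

        m, s = _folded_moments(mu, sigma)
        assert m == pytest.approx(0.38, abs=1e-6)
        assert s == pytest.approx(0.19, abs=1e-6)

    def test_infeasible_moment_pair_rejected(self):
        with pytest.raises(ValueError):
            folded_normal_params(0.1, 0.2)


class TestPairPresets:
    def test_identical_pair_consistent(self):
        meas, calc, manifest = make_pair("identical")
        assert manifest["preset"] == "identical"
        np.testing.assert_allclose(meas.values, 100.0)
        np.testing.assert_allclose(calc.values, 100.0)

    def test_region_error_exact_on_detector(self):
        meas, calc, manifest = make_pair("region-error", magnitude_pct=5.0)
        rr, cc = meas.pixel_positions()
        inside = (np.abs(rr) <= 15) & (np.abs(cc) <= 15)
        np.testing.assert_allclose(meas.values[inside], 105.0)
        np.testing.assert_allclose(meas.values[~inside], 100.0)
        assert inside.sum() == 9  # 3x3 cm^2 region at 7.62 mm pitch

    def test_generation_deterministic(self):
        a = make_pair("noise", magnitude_pct=2.0, seed=5)[0]
        b = make_pair("noise", magnitude_pct=2.0, seed=5)[0]
        np.testing.assert_array_equal(a.values, b.values)

    def test_dome_plane_shape(self):
        plane = dome_plane(half_size_mm=70.0, dose=100.0, edge_drop=0.15)
        assert plane.values.max() == pytest.approx(100.0)
        assert plane.values.min() == pytest.approx(85.0)
        i, j = np.unravel_index(np.argmax(plane.values), plane.shape)
        rr, cc = plane.pixel_positions()
        assert (rr[i, j], cc[i, j]) == (0.0, 0.0)
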