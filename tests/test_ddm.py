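import numpy as np
import pytest

from ddmqa import (
    Criteria,
    DosePlane,
    compute_ddm,
    compute_gamma,
    ddm_heatmap,
    ddm_histogram,
    ddm_pass_rate,
    downsample_to_detector,
    make_pair,
    resample_for_comparison,
    uniform_plane,
)
from ddmqa.ddm import DDMMap
from .conftest import random_plane_pair
from .oracles import brute_ddm


def _uniform_pair(offset=0.0, spacing=0.2):
    calc = uniform_plane(size_mm=60.0, dose=100.0, spacing_mm=1.0)
    meas = downsample_to_detector(calc)
    meas = DosePlane(meas.values + offset, spacing=meas.spacing,
                     origin=meas.origin, label="measured")
    return meas, resample_for_comparison(calc, meas, spacing)


class TestComputeDdm:
    def test_identical_planes_give_zero(self, criteria):
        meas, fine = _uniform_pair()
        dmap = compute_ddm(meas, fine, criteria)
        np.testing.assert_allclose(dmap.evaluated_values, 0.0, atol=1e-12)

    def test_uniform_offset_cannot_escape(self, criteria):
        # a spatially uniform +2% offset has no spatial escape: DDM is +2
        # (signed) at every evaluated pixel
        meas, fine = _uniform_pair(offset=2.0)
        dmap = compute_ddm(meas, fine, criteria)
        np.testing.assert_allclose(dmap.evaluated_values, 2.0, rtol=1e-12)

    def test_gradient_escape_within_radius(self):
        # calculated dose ramps at g %/mm; a measured plane shifted by
        # s < r along the gradient finds a matching dose inside the disk
        g = 2.0  # % of max per mm
        cols = np.arange(81)[None, :] * 1.0
        calc = DosePlane(np.repeat(20.0 + g * cols, 81, axis=0),
                         spacing=(1.0, 1.0), origin=(-40.0, -40.0))
        meas = downsample_to_detector(calc).shifted((0.0, 0.6))
        fine = resample_for_comparison(calc, meas, 0.05)
        crit = Criteria(dose_pct=3.0, distance_mm=2.0, search_radius_mm=1.0)
        dmap = compute_ddm(meas, fine, crit)
        inner = dmap.evaluated_values[~dmap.truncated_mask[dmap.evaluated_mask]]
        assert np.max(np.abs(inner)) < g * 0.05 + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_toy_grids(self, seed):
        rng = np.random.default_rng(seed)
        meas, calc = random_plane_pair(rng, measured_shape=(5, 5), calc_shape=(11, 11))
        crit = Criteria(dose_pct=3.0, distance_mm=2.0, search_radius_mm=1.5)
        dmap = compute_ddm(meas, calc, crit)
        oracle = brute_ddm(meas, calc, crit)
        np.testing.assert_allclose(dmap.values[dmap.evaluated_mask],
                                   oracle[dmap.evaluated_mask], rtol=1e-12)

    def test_magnitude_bounded_by_inplace_difference(self, criteria):
        rng = np.random.default_rng(21)
        calc = DosePlane(rng.uniform(20, 100, (41, 41)), spacing=(1.0, 1.0),
                         origin=(-20.0, -20.0))
        meas = downsample_to_detector(calc, pitch_mm=3.0)
        meas = DosePlane(meas.values * rng.uniform(0.95, 1.05, meas.shape),
                         spacing=meas.spacing, origin=meas.origin)
        fine = resample_for_comparison(calc, meas, 0.2)
        dmap = compute_ddm(meas, fine, criteria)
        interp = fine.interpolator()
        rr, cc = meas.pixel_positions()
        inplace = 100.0 * (meas.values - interp(
            np.stack([rr.ravel(), cc.ravel()], 1)).reshape(meas.shape)) / dmap.max_dose
        mask = dmap.evaluated_mask
        assert np.all(np.abs(dmap.values[mask]) <= np.abs(inplace[mask]) + 1e-9)

    def test_magnitude_nonincreasing_in_radius(self):
        rng = np.random.default_rng(33)
        meas, calc = random_plane_pair(rng)
        maps = [compute_ddm(meas, calc, Criteria(search_radius_mm=r))
                for r in (1.0, 1.5, 2.0)]
        for small, big in zip(maps, maps[1:]):
            mask = small.evaluated_mask
            assert np.all(np.abs(big.values[mask])
                          <= np.abs(small.values[mask]) + 1e-12)

    def test_single_point_limit_equals_dose_difference(self, criteria):
        # with the search grid as fine as the radius, the disk holds only
        # the in-place point (and immediate neighbors of identical dose on
        # a uniform plane): DDM reduces to the point dose difference
        meas, fine = _uniform_pair(offset=1.3, spacing=0.06)
        crit = Criteria(dose_pct=3.0, distance_mm=2.0,
                        search_radius_mm=float(max(fine.spacing)))
        dmap = compute_ddm(meas, fine, crit)
        np.testing.assert_allclose(dmap.evaluated_values, 1.3, rtol=1e-12)

    def test_radius_below_grid_spacing_rejected(self, criteria):
        meas, fine = _uniform_pair(spacing=0.5)
        crit = Criteria(search_radius_mm=0.2)
        with pytest.raises(ValueError):
            compute_ddm(meas, fine, crit)

    def test_tie_breaks_to_positive_sign(self):
        calc = DosePlane(np.tile([[99.0, 102.0, 101.0]], (3, 1)),
                         spacing=(1.0, 1.0), origin=(-1.0, -1.0))
        meas = DosePlane(np.array([[100.0]]), spacing=(1.0, 1.0), origin=(0.0, 0.0))
        crit = Criteria(dose_pct=3.0, search_radius_mm=1.0,
                        max_dose_from="measured")
        dmap = compute_ddm(meas, calc, crit)
        # left neighbor gives +1, right neighbor -1, both at distance 1
        assert dmap.values[0, 0] == 1.0

    def test_truncated_disks_flagged_at_edges(self, criteria):
        meas, fine = _uniform_pair()
        dmap = compute_ddm(meas, fine, criteria)
        assert not dmap.truncated_mask[3, 3]
        # measured pixel nearest the calculated boundary has a clipped disk
        edge = np.abs(meas_edge_distance(meas, fine)) < criteria.search_radius_mm
        assert np.array_equal(dmap.truncated_mask & dmap.evaluated_mask,
                              edge & dmap.evaluated_mask)


def meas_edge_distance(meas, fine):
    """Distance from each measured pixel to the nearest fine-grid border."""
    rr, cc = meas.pixel_positions()
    (r0, r1), (c0, c1) = fine.extent
    return np.minimum.reduce([rr - r0, r1 - rr, cc - c0, c1 - cc])


class TestPassRateAndHistogram:
    def _map(self, values):
        vals = np.atleast_2d(np.asarray(values, float))
        return DDMMap(values=vals, evaluated_mask=np.ones_like(vals, bool),
                      truncated_mask=np.zeros_like(vals, bool), r_mm=1.0,
                      max_dose=100.0, criteria=Criteria())

    def test_pass_rate_toys(self):
        assert ddm_pass_rate(self._map([0.0, 0.0])) == 100.0
        assert ddm_pass_rate(self._map([5.0, 5.0])) == 0.0
        assert ddm_pass_rate(self._map([-4.0, 1.0, 2.9, 3.1])) == 50.0

    def test_boundary_strictness(self):
        at_tol = self._map([3.0])
        assert ddm_pass_rate(at_tol) == 0.0
        assert ddm_pass_rate(at_tol, boundary_passes=True) == 100.0

    def test_histogram_all_zero(self):
        h = ddm_histogram(self._map(np.zeros((4, 4))))
        assert h.mu == 0.0 and h.sigma == 0.0
        assert h.counts.sum() == 16
        assert np.count_nonzero(h.counts) == 1
        assert h.bin_centers[h.counts > 0] == pytest.approx([0.0])

    def test_histogram_symmetric_pair(self):
        h = ddm_histogram(self._map([-1.0, 1.0]))
        assert h.mu == 0.0
        assert h.sigma == 1.0

    def test_histogram_moments_match_direct_formulas(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0.5, 2.0, size=(8, 8))
        h = ddm_histogram(self._map(vals))
        assert h.mu == pytest.approx(vals.mean())
        assert h.sigma == pytest.approx(vals.std())
        assert h.counts.sum() == vals.size
        assert h.bin_edges[0] <= vals.min() and h.bin_edges[-1] >= vals.max()

    def test_histogram_rejects_bad_bin_width(self):
        with pytest.raises(ValueError):
            ddm_histogram(self._map([1.0]), bin_width_pct=0.0)

    def test_larger_radius_never_adds_out_of_tolerance_mass(self):
        # the large-search-distance artifact: counts beyond any deviation
        # level only shrink when r grows (per-pixel magnitudes shrink)
        meas, calc, _ = make_pair("noise", magnitude_pct=2.0, seed=4)
        fine = resample_for_comparison(calc, meas, 0.2)
        small = compute_ddm(meas, fine, Criteria(search_radius_mm=1.0))
        big = compute_ddm(meas, fine, Criteria(search_radius_mm=2.0))
        for level in np.arange(3.0, 10.0, 0.5):
            assert (np.count_nonzero(np.abs(big.evaluated_values) >= level)
                    <= np.count_nonzero(np.abs(small.evaluated_values) >= level))


class TestHeatmap:
    def test_asterisks_match_gamma_failures(self, criteria):
        import matplotlib

        matplotlib.use("Agg")
        meas, calc, _ = make_pair("region-error", magnitude_pct=8.0)
        fine = resample_for_comparison(calc, meas, 0.2)
        dmap = compute_ddm(meas, fine, criteria)
        gmap = compute_gamma(meas, fine, criteria)
        n_fail = int(np.count_nonzero(gmap.evaluated_mask & (gmap.values > 1)))
        ax, disp = ddm_heatmap(dmap, gamma_map=gmap, measured=meas)
        assert len(ax.lines[-1].get_xdata()) == n_fail
        assert n_fail > 0
        assert disp.shape == meas.shape

    def test_clean_map_has_no_asterisks(self, criteria):
        import matplotlib

        matplotlib.use("Agg")
        meas, calc, _ = make_pair("identical")
        fine = resample_for_comparison(calc, meas, 0.2)
        dmap = compute_ddm(meas, fine, criteria)
        gmap = compute_gamma(meas, fine, criteria)
        ax, disp = ddm_heatmap(dmap, gamma_map=gmap)
        assert len(ax.lines[-1].get_xdata()) == 0
        np.testing.assert_allclose(disp[dmap.evaluated_mask], 0.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, criteria):
        dmap = TestPassRateAndHistogram()._map(np.zeros((2, 2)))
        meas, fine = _uniform_pair()
        gmap = compute_gamma(meas, fine, criteria)
        with pytest.raises(ValueError):
            ddm_heatmap(dmap, gamma_map=gmap)
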