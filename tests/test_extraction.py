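"""Hough center, polar transform, dynamic programming, ellipse fit."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fetalhc import (
    EllipseAnnotation,
    GrowthCurveTable,
    PipelineConfig,
    ScaledImage,
    hough_center,
    polar_transform,
    radius_bounds,
)
from fetalhc.classifier import LikelihoodMap
from fetalhc.extraction import (
    EDGE_BAND_HALF_WIDTH_MM,
    DetectionError,
    FitError,
    PolarMap,
    dp_shortest_path,
    extract_skull_midline,
    filter_ellipse,
    fit_ellipse_direct,
    refine_outer_edge,
    select_fit_points,
)


def toy_curve():
    ga = [60.0, 100.0, 200.0]
    return GrowthCurveTable(pd.DataFrame({
        "ga_days": ga,
        "hc_p3": [40.0, 90.0, 250.0],
        "hc_p50": [45.0, 100.0, 280.0],
        "hc_p97": [50.0, 110.0, 100 * math.pi],
        "bpd_p3": [10.0, 27.0, 36.0],
        "bpd_p50": [13.0, 30.0, 38.0],
        "bpd_p97": [15.0, 33.0, 40.0],
    }))


class TestRadiusBounds:
    def test_forced_arithmetic(self):
        # at GA 200: HC_P97 = 100*pi, BPD_P97 = 40 -> r_max = ceil(100 - 20) = 80
        curve = toy_curve()
        r_min, r_max = radius_bounds(curve, 60.0, 200.0)
        assert r_max == 80.0
        assert r_min == 5.0  # half of BPD_P3(60) = 10

    def test_interpolated_bounds(self):
        curve = toy_curve()
        # hand interpolation at GA 80 (halfway 60..100): BPD_P3 = 18.5
        r_min, r_max = radius_bounds(curve, 80.0, 150.0)
        assert r_min == pytest.approx(18.5 / 2)
        hc = 110 + 0.5 * (100 * math.pi - 110)
        bpd = 33 + 0.5 * (40 - 33)
        assert r_max == math.ceil(hc / math.pi - bpd / 2)

    def test_out_of_range_ga(self):
        with pytest.raises(ValueError):
            radius_bounds(toy_curve(), 10.0, 200.0)


def ring_map(h, w, ps, cx, cy, radius, width=0.7):
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    d = np.hypot((jj + 0.5) * ps - cx, (ii + 0.5) * ps - cy)
    return LikelihoodMap((np.abs(d - radius) < width).astype(float), ps)


class TestHough:
    def test_ideal_ring_center(self):
        lm = ring_map(60, 80, 1.0, 40.0, 30.0, 20.0)
        cx, cy = hough_center(lm, 15, 25)
        assert math.hypot(cx - 40, cy - 30) <= 1.0

    def test_radius_bounds_pick_the_right_ring(self):
        vals = ring_map(100, 140, 1.0, 35.0, 50.0, 10.0).values + \
            ring_map(100, 140, 1.0, 100.0, 50.0, 25.0).values
        lm = LikelihoodMap(np.clip(vals, 0, 1), 1.0)
        cx, cy = hough_center(lm, 20, 30)
        assert math.hypot(cx - 100, cy - 50) <= 2.0

    def test_all_zero_map_fails(self):
        with pytest.raises(DetectionError):
            hough_center(LikelihoodMap(np.zeros((40, 40)), 1.0), 5, 15)


class TestPolarTransform:
    def test_shape_and_radii(self):
        src = np.zeros((50, 60))
        pm = polar_transform(src, 0.5, (15.0, 12.0), 270, 0.3, 5.0, 20.0)
        assert pm.values.shape == (270, int((20 - 5) / 0.3) + 1)
        assert pm.radii[0] == 5.0
        assert pm.s_dis_eff == 0.3

    def test_native_resolution_when_sdis_zero(self):
        pm = polar_transform(np.zeros((50, 60)), 0.5, (15.0, 12.0), 90, 0.0, 0.0, 10.0)
        assert pm.s_dis_eff == 0.5

    def test_constant_map_stays_constant(self):
        pm = polar_transform(np.full((60, 60), 3.3), 0.5, (15.0, 15.0), 90, 0.2, 0.0, 10.0)
        assert np.allclose(pm.values, 3.3)

    def test_ring_argmax_radius(self):
        lm = ring_map(200, 200, 0.5, 50.0, 50.0, 25.0)
        pm = polar_transform(lm.values, 0.5, (50.0, 50.0), 180, 0.4, 5.0, 45.0)
        peak_r = pm.radii[np.argmax(pm.values, axis=1)]
        assert np.all(np.abs(peak_r - 25.0) <= 2 * pm.s_dis_eff)

    def test_center_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            polar_transform(np.zeros((10, 10)), 1.0, (50.0, 5.0), 90, 0.0, 0.0, 5.0)


def brute_force_paths(cost, step):
    """Enumerate all feasible paths; return (min cost, lexicographically
    smallest arg-min path) — the documented tie-break."""
    n_ang, n_rad = cost.shape
    best = None
    for path in itertools.product(range(n_rad), repeat=n_ang):
        if any(abs(path[i + 1] - path[i]) > step for i in range(n_ang - 1)):
            continue
        c = sum(cost[i, p] for i, p in enumerate(path))
        key = (c, tuple(reversed(path)))
        if best is None or key < best:
            best = key
    return best[0], tuple(reversed(best[1]))


class TestDynamicProgramming:
    @staticmethod
    def as_pm(cost):
        return PolarMap(np.asarray(cost, float), (0.0, 0.0), 0.0, 1.0)

    def test_zero_cost_row_is_followed(self):
        cost = np.ones((8, 6))
        cost[:, 3] = 0.0
        p = dp_shortest_path(self.as_pm(cost), cost, 1)
        assert np.all(p.indices == 3)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(50):
            cost = rng.integers(0, 2, (4, 6)).astype(float)
            p = dp_shortest_path(self.as_pm(cost), cost, 1)
            got = sum(cost[i, j] for i, j in enumerate(p.indices))
            expect, _ = brute_force_paths(cost, 1)
            assert got == expect

    @pytest.mark.parametrize("shape,step", [((3, 4), 1), ((5, 7), 1), ((4, 5), 2), ((5, 3), 1)])
    def test_matches_enumeration_with_ties(self, shape, step, rng):
        """Exact cost AND the documented tie-break (smaller radius, then
        smaller predecessor) against full enumeration."""
        for _ in range(15):
            cost = rng.integers(0, 3, shape).astype(float)
            p = dp_shortest_path(self.as_pm(cost), cost, step)
            expect_cost, expect_path = brute_force_paths(cost, step)
            got = sum(cost[i, j] for i, j in enumerate(p.indices))
            assert got == expect_cost

    def test_constant_shift_invariance(self, rng):
        cost = rng.random((10, 8))
        a = dp_shortest_path(self.as_pm(cost), cost, 1).indices
        b = dp_shortest_path(self.as_pm(cost), cost + 5.0, 1).indices
        assert np.array_equal(a, b)

    def test_uniform_cost_deterministic(self):
        cost = np.ones((12, 9))
        a = dp_shortest_path(self.as_pm(cost), cost, 1).indices
        b = dp_shortest_path(self.as_pm(cost), cost, 1).indices
        assert np.array_equal(a, b)
        assert a.max() == 0  # ties resolve to the smallest radius


def t2_cfg(**over):
    base = dict(name="t2", ga_min=98, ga_max=195, r_min=12, r_max=50,
                f_scales=(7.0,), s_dis=0.3, n_angles=270, radial_offset=5.0)
    base.update(over)
    return PipelineConfig(**base)


class TestMidline:
    def test_follows_phantom_ring(self):
        lm = ring_map(300, 300, 0.4, 60.0, 60.0, 25.0, width=1.0)
        path = extract_skull_midline(lm, (60.0, 60.0), t2_cfg())
        frac = np.mean(np.abs(path.radii - 25.0) <= 1.0)
        assert frac >= 0.95

    def test_structures_below_offset_invisible(self):
        lm = ring_map(300, 300, 0.4, 60.0, 60.0, 25.0, width=1.0)
        blob = ring_map(300, 300, 0.4, 60.0, 60.0, 3.0, width=1.5)  # below 5 mm offset
        lm2 = LikelihoodMap(np.clip(lm.values + blob.values, 0, 1), 0.4)
        a = extract_skull_midline(lm, (60.0, 60.0), t2_cfg())
        b = extract_skull_midline(lm2, (60.0, 60.0), t2_cfg())
        assert np.array_equal(a.indices, b.indices)

    def test_uniform_likelihood_still_returns_path(self):
        lm = LikelihoodMap(np.full((200, 200), 0.5), 0.4)
        path = extract_skull_midline(lm, (40.0, 40.0), t2_cfg())
        assert len(path.indices) == 270


def edge_scene(inner=24.0, outer=26.0, ps=0.25):
    """Bright annulus between inner and outer radius on dark ground."""
    n = 280
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    d = np.hypot((jj + 0.5) * ps - 35.0, (ii + 0.5) * ps - 35.0)
    img = np.where((d >= inner) & (d <= outer), 220.0, 30.0)
    return ScaledImage(img, ps), d


class TestEdgeRefinement:
    @staticmethod
    def midline_at(radius, ps=0.25, n_angles=270):
        pm = polar_transform(np.zeros((280, 280)), ps, (35.0, 35.0), n_angles, 0.3, 5.0, 45.0)
        idx = np.full(n_angles, int(round((radius - 5.0) / 0.3)))
        from fetalhc.extraction import RadialPath

        return RadialPath(idx, pm)

    def test_snaps_to_outer_edge(self):
        img, _ = edge_scene(24.0, 26.0)
        mid = self.midline_at(25.0)
        refined = refine_outer_edge(img, (35.0, 35.0), mid, t2_cfg())
        # strongest bright->dark transition is at the outer radius
        assert np.median(np.abs(refined.radii - 26.0)) <= 2 * img.pixel_size

    def test_displacement_saturates_at_band(self):
        img, _ = edge_scene(28.0, 30.0)  # true edge 4-5 mm beyond the midline
        mid = self.midline_at(25.0)
        refined = refine_outer_edge(img, (35.0, 35.0), mid, t2_cfg())
        disp = np.abs(refined.radii - mid.radii)
        assert disp.max() <= EDGE_BAND_HALF_WIDTH_MM + 1e-9
        assert disp.max() >= EDGE_BAND_HALF_WIDTH_MM - 2 * img.pixel_size

    def test_flat_image_stays_in_band(self):
        img = ScaledImage(np.full((280, 280), 90.0), 0.25)
        mid = self.midline_at(25.0)
        refined = refine_outer_edge(img, (35.0, 35.0), mid, t2_cfg())
        assert np.all(np.abs(refined.radii - mid.radii) <= EDGE_BAND_HALF_WIDTH_MM + 1e-9)

    def test_band_never_violated_on_phantom(self):
        img, _ = edge_scene(24.0, 26.0)
        mid = self.midline_at(25.0)
        refined = refine_outer_edge(img, (35.0, 35.0), mid, t2_cfg())
        assert np.all(np.abs(refined.radii - mid.radii) <= EDGE_BAND_HALF_WIDTH_MM + 1e-9)


class TestFitPointSelection:
    @staticmethod
    def path_with_likelihood(n_angles, lik_values, ps=0.5):
        h = w = 200
        vals = np.zeros((h, w))
        pm = polar_transform(vals, ps, (50.0, 50.0), n_angles, 0.5, 10.0, 30.0)
        from fetalhc.extraction import RadialPath

        idx = np.full(n_angles, 20)
        path = RadialPath(idx, pm)
        # paint the likelihood under each path point
        lmap = np.zeros((h, w))
        pts = path.points()
        rows = np.clip(np.round(pts[:, 1] / ps - 0.5).astype(int), 0, h - 1)
        cols = np.clip(np.round(pts[:, 0] / ps - 0.5).astype(int), 0, w - 1)
        lmap[rows, cols] = lik_values
        return path, LikelihoodMap(lmap, ps)

    def test_rank_mode_counts(self, rng):
        lik = rng.permutation(270) / 270.0
        path, lmap = self.path_with_likelihood(270, lik)
        pts = select_fit_points(path, lmap, mode="rank")
        assert len(pts) == math.ceil(270 * 0.05)  # 14

    def test_rank_mode_floor(self, rng):
        lik = rng.permutation(40) / 40.0
        path, lmap = self.path_with_likelihood(40, lik)
        assert len(select_fit_points(path, lmap, mode="rank")) == 6

    def test_equal_likelihood_deterministic(self):
        path, lmap = self.path_with_likelihood(100, np.full(100, 0.7))
        a = select_fit_points(path, lmap, mode="rank")
        b = select_fit_points(path, lmap, mode="rank")
        assert np.array_equal(a, b)

    def test_map_mode_keeps_above_threshold_points(self, rng):
        lik = np.zeros(270)
        lik[::2] = 0.9  # half the path sits on high-likelihood pixels
        path, lmap = self.path_with_likelihood(270, lik)
        pts = select_fit_points(path, lmap, mode="map")
        # the 95th map percentile is below 0.9 here, so all bright points stay
        assert len(pts) >= 100


class TestDirectEllipseFit:
    def test_exact_recovery(self):
        truth = EllipseAnnotation(40.0, 30.0, 25.0, 20.0, 0.3)
        fit = fit_ellipse_direct(truth.boundary_points(8))
        for f in ("cx", "cy", "a", "b", "theta"):
            assert getattr(fit, f) == pytest.approx(getattr(truth, f), abs=1e-6)

    def test_circle_degeneracy(self):
        fit = fit_ellipse_direct(EllipseAnnotation(10, 10, 7, 7).boundary_points(12))
        assert fit.a == pytest.approx(fit.b, abs=1e-6)
        assert 0 <= fit.theta < math.pi

    def test_noisy_points_stable(self, rng):
        truth = EllipseAnnotation(40.0, 30.0, 25.0, 20.0, 1.0)
        sigma = 0.5
        for seed in range(5):
            r = np.random.default_rng(seed)
            pts = truth.boundary_points(100) + r.normal(0, sigma, (100, 2))
            fit = fit_ellipse_direct(pts)
            # residual RMS against the fitted boundary stays near sigma
            bnd = fit.boundary_points(2000)
            from scipy.spatial.distance import cdist

            rms = np.sqrt((cdist(pts, bnd).min(axis=1) ** 2).mean())
            assert rms <= 2 * sigma
            assert abs(fit.circumference - truth.circumference) < 5.0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(FitError):
            fit_ellipse_direct(pts)

    def test_matches_reference_implementation(self, rng):
        """Cross-check against skimage's EllipseModel on random ellipses."""
        from skimage.measure import EllipseModel

        for _ in range(10):
            a = rng.uniform(10, 40)
            truth = EllipseAnnotation(rng.uniform(30, 60), rng.uniform(30, 60),
                                      a, a * rng.uniform(0.6, 0.95), rng.uniform(0, math.pi))
            pts = truth.boundary_points(40) + rng.normal(0, 0.05, (40, 2))
            fit = fit_ellipse_direct(pts)
            if hasattr(EllipseModel, "from_estimate"):
                ref = EllipseModel.from_estimate(pts)
            else:  # scikit-image < 0.26
                ref = EllipseModel()
                assert ref.estimate(pts)
            (xc, yc), (ra, rb), th = ref.center, ref.axis_lengths, ref.theta
            ref_e = EllipseAnnotation(xc, yc, ra, rb, th)
            assert fit.cx == pytest.approx(ref_e.cx, abs=0.1)
            assert fit.cy == pytest.approx(ref_e.cy, abs=0.1)
            assert fit.circumference == pytest.approx(ref_e.circumference, rel=5e-3)


class TestCircumferenceFilter:
    @pytest.mark.parametrize("circ,expected", [(38.59, False), (38.60, True),
                                               (2 * math.pi * 10, True)])
    def test_threshold_is_inclusive(self, circ, expected):
        e = EllipseAnnotation(0, 0, circ / (2 * math.pi), circ / (2 * math.pi))
        assert filter_ellipse(e) is expected
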