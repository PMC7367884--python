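"""Morphometric descriptors: optical density, boundaries, thickness,
surface factor, Mann-Whitney."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryostack import (
    BoundaryPolyline,
    mann_whitney_u,
    optical_density,
    radial_thickness,
    rgb_profile,
    split_slab_boundaries,
    surface_factor,
    trace_boundary,
)


def circle_polyline(radius, n=4096, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n + 1)
    pts = np.stack([center[0] + radius * np.cos(th),
                    center[1] + radius * np.sin(th)], axis=-1)
    return BoundaryPolyline(pts, closed=True)


class TestOpticalDensity:
    @pytest.mark.parametrize("rgb,expected", [
        ((100, 100, 100), 100.0),
        ((0, 0, 0), 0.0),
        ((255, 0, 0), 76.245),
    ])
    def test_printed_weights(self, rgb, expected):
        assert optical_density(rgb) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 255))
    @settings(max_examples=30, deadline=None)
    def test_gray_is_identity(self, c):
        assert optical_density((c, c, c)) == pytest.approx(c, abs=1e-9)

    def test_channel_order_matters(self):
        assert optical_density((255, 0, 0)) < optical_density((0, 255, 0))
        assert optical_density((0, 0, 255)) < optical_density((255, 0, 0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            optical_density((300, 0, 0))
        with pytest.raises(ValueError, match="channel"):
            optical_density((0, -1, 0))


class TestRgbProfile:
    def test_uniform_region(self):
        img = np.full((8, 8, 3), (10, 20, 30), dtype=np.uint8)
        assert rgb_profile(img) == (10.0, 20.0, 30.0)

    def test_half_and_half_average(self):
        img = np.zeros((2, 2, 3), np.uint8)
        img[0] = (200, 100, 50)
        assert rgb_profile(img) == (100.0, 50.0, 25.0)

    def test_single_pixel_mask(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[1, 2] = (5, 6, 7)
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        assert rgb_profile(img, mask) == (5.0, 6.0, 7.0)

    def test_empty_mask_rejected(self):
        img = np.zeros((4, 4, 3), np.uint8)
        with pytest.raises(ValueError, match="empty mask"):
            rgb_profile(img, np.zeros((4, 4), bool))


class TestTraceBoundary:
    def test_disc_gives_closed_contour_near_circumference(self):
        n, r = 128, 40
        yy, xx = np.mgrid[0:n, 0:n]
        mask = (xx - 64) ** 2 + (yy - 64) ** 2 <= r * r
        (b,) = trace_boundary(mask, pitch_um=2.0)
        assert b.closed
        # marching squares on binary data overshoots the true perimeter by
        # a few percent (staircase bias); stays within 8%
        assert b.arc_length == pytest.approx(2 * np.pi * r * 2.0, rel=0.08)

    def test_full_frame_mask_gives_frame_rectangle(self):
        mask = np.ones((10, 12), bool)
        (b,) = trace_boundary(mask, pitch_um=1.0)
        assert b.closed
        assert b.vertices[:, 0].min() >= -0.5
        assert b.vertices[:, 0].max() <= 11.5

    def test_two_discs_give_two_polylines(self):
        mask = np.zeros((40, 80), bool)
        yy, xx = np.mgrid[0:40, 0:80]
        mask |= (xx - 20) ** 2 + (yy - 20) ** 2 <= 64
        mask |= (xx - 60) ** 2 + (yy - 20) ** 2 <= 64
        assert len(trace_boundary(mask)) == 2

    def test_empty_mask_gives_empty_list(self):
        assert trace_boundary(np.zeros((5, 5), bool)) == []


class TestSurfaceFactor:
    def test_straight_boundary_is_exactly_one(self):
        line = BoundaryPolyline(np.array([[0.0, 0.0], [500.0, 0.0]]))
        res = surface_factor(line, spacing_um=100.0)
        assert res.n_segments == 5
        assert np.all(res.factors == 1.0)

    def test_circle_closed_form(self):
        # chord 100 on R=100 circle spans theta = pi/3: factor = pi/3
        res = surface_factor(circle_polyline(100.0), spacing_um=100.0)
        assert res.mean == pytest.approx(np.pi / 3, abs=1e-3)

    def test_sinusoid_matches_quadrature_oracle(self):
        from scipy.integrate import quad

        a, lam = 30.0, 400.0
        x = np.linspace(0.0, 1600.0, 6001)
        poly = BoundaryPolyline(
            np.stack([x, a * np.sin(2 * np.pi * x / lam)], axis=-1))
        res = surface_factor(poly, spacing_um=100.0)

        # oracle: walk the continuous curve with scipy quadrature + bisection
        k = 2 * np.pi / lam
        def arc(x0, x1):
            return quad(lambda t: np.sqrt(1 + (a * k * np.cos(k * t)) ** 2),
                        x0, x1, limit=200)[0]
        def chord(x0, x1):
            return np.hypot(x1 - x0, a * np.sin(k * x1) - a * np.sin(k * x0))
        from scipy.optimize import brentq

        factors, x0 = [], 0.0
        while True:
            hi = x0 + 200.0
            if hi > 1600.0:
                break
            x1 = brentq(lambda t: chord(x0, t) - 100.0, x0 + 25.0, hi)
            factors.append(arc(x0, x1) / 100.0)
            x0 = x1
        assert res.mean == pytest.approx(np.mean(factors), rel=0.01)

    def test_factors_at_least_one_on_random_smooth_boundaries(self, rng):
        # random Fourier-smooth closed curves
        for _ in range(200):
            th = np.linspace(0, 2 * np.pi, 600)
            r = 150.0 + sum(rng.uniform(0, 12) * np.sin(m * th + rng.uniform(0, 2 * np.pi))
                            for m in range(1, 5))
            pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
            res = surface_factor(BoundaryPolyline(pts, closed=True), 100.0)
            assert np.all(res.factors >= 1.0 - 1e-12)

    def test_too_short_boundary_rejected(self):
        line = BoundaryPolyline(np.array([[0.0, 0.0], [50.0, 0.0]]))
        with pytest.raises(ValueError, match="shorter"):
            surface_factor(line, spacing_um=100.0)


class TestRadialThickness:
    def test_concentric_circles_constant_thickness(self):
        outer = circle_polyline(300.0, n=8000)
        inner = circle_polyline(100.0, n=8000)
        res = radial_thickness(outer, inner, n_rays=64)
        assert res.n_missed == 0
        assert res.median == pytest.approx(200.0, abs=1e-3)
        assert np.ptp(res.values_um) <= 1e-6 * res.median

    def test_parallel_lines_slab(self):
        outer = BoundaryPolyline(np.array([[0.0, 0.0], [2000.0, 0.0]]))
        inner = BoundaryPolyline(np.array([[-50.0, 232.0], [2050.0, 232.0]]))
        res = radial_thickness(outer, inner, n_rays=32)
        assert res.n_missed == 0
        np.testing.assert_allclose(res.values_um, 232.0, atol=1e-9)

    def test_identical_boundaries_measure_zero(self):
        outer = circle_polyline(100.0, n=512)
        res = radial_thickness(outer, outer, n_rays=16)
        np.testing.assert_allclose(res.values_um, 0.0, atol=1e-9)

    def test_missed_rays_counted(self):
        outer = circle_polyline(300.0, n=1000)
        # tiny inner arc far from most rays
        inner = BoundaryPolyline(np.array([[95.0, -5.0], [95.0, 5.0]]))
        res = radial_thickness(outer, inner, n_rays=64)
        assert res.n_missed > 0
        assert len(res.values_um) + res.n_missed == 64

    def test_summary_quartiles(self):
        outer = BoundaryPolyline(np.array([[0.0, 0.0], [1000.0, 0.0]]))
        inner = BoundaryPolyline(np.array([[-50.0, 100.0], [1050.0, 100.0]]))
        res = radial_thickness(outer, inner, n_rays=9)
        assert res.q1 <= res.median <= res.q3
        assert "100.0 [" in res.summary()


def test_split_slab_boundaries_orders_outer_then_inner():
    mask = np.zeros((60, 100), bool)
    mask[20:49, 5:95] = True
    (contour,) = trace_boundary(mask, pitch_um=8.0)
    outer, inner = split_slab_boundaries(contour)
    assert outer.vertices[:, 1].mean() < inner.vertices[:, 1].mean()
    res = radial_thickness(outer, inner, n_rays=24)
    assert res.median == pytest.approx(29 * 8.0, abs=8.0)


def brute_force_mann_whitney(a, b):
    """Oracle: pairwise win counting over every labeling of the pooled
    values (independent of the rank-based implementation)."""
    pooled = list(a) + list(b)
    n_a, n_b = len(a), len(b)

    def u_stat(group_a, group_b):
        wins = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    wins += 1.0
                elif x == y:
                    wins += 0.5
        return wins

    u_a_obs = u_stat(a, b)
    u_obs = min(u_a_obs, n_a * n_b - u_a_obs)
    mu = n_a * n_b / 2.0
    dev = abs(u_a_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(grp_a, grp_b) - mu) >= dev - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_fully_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_two_sided == 1.0

    def test_interleaved_example_matches_enumeration(self):
        res = mann_whitney_u([1, 3], [2, 4])
        u, p = brute_force_mann_whitney([1, 3], [2, 4])
        assert res.u == u
        assert res.p_two_sided == pytest.approx(p, abs=1e-12)

    def test_matches_enumeration_oracle_with_and_without_ties(self, rng):
        for na, nb in [(1, 3), (2, 2), (3, 4), (4, 4), (2, 6)]:
            a = rng.integers(0, 6, na).astype(float)  # ints force ties
            b = rng.integers(0, 6, nb).astype(float)
            res = mann_whitney_u(a, b)
            u, p = brute_force_mann_whitney(a, b)
            assert res.u == pytest.approx(u, abs=1e-12)
            assert res.p_two_sided == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        from scipy.stats import mannwhitneyu

        for na, nb in [(3, 3), (2, 5), (4, 4), (3, 6)]:
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + 0.5
            res = mann_whitney_u(a, b)
            ref = mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert res.p_two_sided == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(size=20)
        b = rng.normal(size=25) + 0.6
        res = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic", alternative="two-sided")
        assert res.method == "normal"
        assert res.p_two_sided == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])
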