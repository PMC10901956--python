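"""Adaptation distance measures, hybrid thickness and group statistics."""

import numpy as np
import pytest

from osteoadapt import morphometry
from osteoadapt.contours import (
    ENDOSTEAL,
    PERIOSTEAL,
    Contour,
    circle_contour,
    interpolate_fourfold,
    resample_contour,
    rotate_points,
)


def brute_force_min_distance(adapted_xy, baseline_xy):
    """Independent all-pairs oracle: fourfold-interpolated baseline."""
    base4 = []
    n = len(baseline_xy)
    for i in range(n):
        a, b = baseline_xy[i], baseline_xy[(i + 1) % n]
        for t in (0.0, 0.25, 0.5, 0.75):
            base4.append(a + t * (b - a))
    base4 = np.array(base4)
    out = np.empty(len(adapted_xy))
    for i, p in enumerate(adapted_xy):
        out[i] = np.sqrt(((base4 - p) ** 2).sum(axis=1)).min()
    return out


class TestSurfaceAdaptation:
    def test_concentric_offset_periosteal_positive(self):
        base = circle_contour(100.0, 200, surface=PERIOSTEAL)
        grown = circle_contour(110.0, 200, surface=PERIOSTEAL)
        d = morphometry.surface_adaptation(grown, base)
        np.testing.assert_allclose(d, 10.0, atol=0.05)

    def test_identical_contours_zero(self):
        base = circle_contour(100.0, 200, surface=ENDOSTEAL)
        d = morphometry.surface_adaptation(base, base)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_endosteal_sign_formation_is_marrowward(self):
        base = circle_contour(100.0, 200, surface=ENDOSTEAL)
        shrunk = circle_contour(90.0, 200, surface=ENDOSTEAL)  # marrow shrinks: formation
        grown = circle_contour(110.0, 200, surface=ENDOSTEAL)  # marrow enlarges: resorption
        assert morphometry.surface_adaptation(shrunk, base).mean() == pytest.approx(10.0, abs=0.1)
        assert morphometry.surface_adaptation(grown, base).mean() == pytest.approx(-10.0, abs=0.1)

    def test_translated_square_matches_brute_force(self):
        sq = np.array([[50.0, -50.0], [-50.0, -50.0], [-50.0, 50.0], [50.0, 50.0]])
        base = resample_contour(Contour(sq, surface=PERIOSTEAL), 80)
        adapted = base.with_xy(base.xy + np.array([5.0, 0.0]))
        got = np.abs(morphometry.surface_adaptation(adapted, base))
        oracle = brute_force_min_distance(adapted.xy, base.xy)
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_surface_mismatch_rejected(self):
        a = circle_contour(10.0, 32, surface=PERIOSTEAL)
        b = circle_contour(10.0, 32, surface=ENDOSTEAL)
        with pytest.raises(morphometry.MeasurementError):
            morphometry.surface_adaptation(a, b)


def dense_ray_thickness_oracle(peri, endo, n_ray=10_000):
    """Independent thickness oracle: dense sampling along the inward normal.

    For each periosteal point, walks the inward normal in tiny steps and
    reports min(distance to first cortical-edge crossing, min distance to
    the fourfold endosteal points).
    """
    from osteoadapt.contours import surface_normals

    endo4 = interpolate_fourfold(endo.xy)
    inward = -surface_normals(peri)
    span = 2.2 * (peri.xy.max() - peri.xy.min())
    ts = np.linspace(0, span, n_ray)

    def seg_cross(o, d):
        best = np.inf
        for ring in (peri.xy, endo.xy):
            n = len(ring)
            for i in range(n):
                a, b = ring[i], ring[(i + 1) % n]
                e = b - a
                den = d[0] * e[1] - d[1] * e[0]
                if abs(den) < 1e-14:
                    continue
                ao = a - o
                t = (ao[0] * e[1] - ao[1] * e[0]) / den
                u = (ao[0] * d[1] - ao[1] * d[0]) / den
                if 0.0 <= u <= 1.0 and t > 1e-6 and t < best:
                    best = t
        return best

    out = np.empty(peri.n)
    for i in range(peri.n):
        m1 = np.sqrt(((endo4 - peri.xy[i]) ** 2).sum(axis=1)).min()
        m2 = seg_cross(peri.xy[i], inward[i])
        out[i] = min(m1, m2)
    del ts
    return out


class TestHybridThickness:
    def test_concentric_circles_exact(self):
        peri = circle_contour(150.0, 120, surface=PERIOSTEAL)
        endo = circle_contour(100.0, 120, surface=ENDOSTEAL)
        th = morphometry.hybrid_thickness(peri, endo)
        np.testing.assert_allclose(th, 50.0, atol=0.05)

    def test_eccentric_circles_match_dense_ray_oracle(self):
        peri = circle_contour(150.0, 80, surface=PERIOSTEAL)
        endo = circle_contour(100.0, 80, center=(20.0, 0.0), surface=ENDOSTEAL)
        th = morphometry.hybrid_thickness(peri, endo)
        oracle = dense_ray_thickness_oracle(peri, endo)
        np.testing.assert_allclose(th, oracle, atol=0.5)

    def test_ridge_normal_recrosses_periosteum_first(self):
        """On the flank of a tall narrow ridge the inward ray exits through
        the opposite ridge wall (a periosteal crossing) before reaching the
        endosteum; the hybrid value must take that shorter crossing and be
        strictly below measurement 1."""
        n = 128
        theta = -np.pi / 2 - 2 * np.pi * np.arange(n) / n
        r = 150.0 + 80.0 * np.exp(-0.5 * (np.angle(np.exp(1j * (theta - np.pi / 2))) / 0.12) ** 2)
        peri = Contour(
            np.column_stack([r * np.cos(theta), r * np.sin(theta)]), surface=PERIOSTEAL
        )
        endo = circle_contour(70.0, n, surface=ENDOSTEAL)
        th, m1, m2, fallback = morphometry.hybrid_thickness(peri, endo, return_components=True)
        oracle = dense_ray_thickness_oracle(peri, endo)
        np.testing.assert_allclose(th, oracle, atol=0.5)
        # flank points beside the notch see the opposite notch wall first
        flank = (m2 < m1 - 1.0) & ~fallback
        assert flank.any()
        assert np.all(th[flank] == m2[flank])


class TestThicknessChange:
    def test_identical_pairs_zero(self):
        pair = (
            circle_contour(150.0, 100, surface=PERIOSTEAL),
            circle_contour(100.0, 100, surface=ENDOSTEAL),
        )
        np.testing.assert_allclose(morphometry.thickness_change(pair, pair), 0.0, atol=1e-12)

    def test_periosteal_inflation_thickens(self):
        control = (
            circle_contour(150.0, 100, surface=PERIOSTEAL),
            circle_contour(100.0, 100, surface=ENDOSTEAL),
        )
        loaded = (
            circle_contour(160.0, 100, surface=PERIOSTEAL),
            circle_contour(100.0, 100, surface=ENDOSTEAL),
        )
        d = morphometry.thickness_change(loaded, control)
        np.testing.assert_allclose(d, 10.0, atol=0.1)

    def test_uniform_endosteal_resorption_thins(self):
        """Marrow enlarged by 21.9 μm with the periosteum unchanged thins
        the cortex by the same amount at every point."""
        control = (
            circle_contour(600.0, 200, surface=PERIOSTEAL),
            circle_contour(400.0, 200, surface=ENDOSTEAL),
        )
        loaded = (
            circle_contour(600.0, 200, surface=PERIOSTEAL),
            circle_contour(421.9, 200, surface=ENDOSTEAL),
        )
        d = morphometry.thickness_change(loaded, control)
        np.testing.assert_allclose(d, -21.9, atol=0.1)


class TestGroupStats:
    def test_identical_nonzero_samples_significant(self):
        field = np.tile(np.full(50, 3.0), (6, 1))
        stats = morphometry.pointwise_stats(field)
        assert np.all(stats.sd == 0.0)
        assert np.all(stats.significant)

    def test_all_zero_samples_not_significant(self):
        stats = morphometry.pointwise_stats(np.zeros((6, 50)))
        assert not stats.significant.any()

    def test_mean_is_linear_under_mirroring(self, rng):
        samples = rng.normal(0, 5, (6, 40))
        s1 = morphometry.pointwise_stats(samples)
        s2 = morphometry.pointwise_stats(-samples)
        np.testing.assert_allclose(s2.mean, -s1.mean)
        np.testing.assert_allclose(s2.p_value, s1.p_value)

    def test_single_mouse_mean_only(self):
        stats = morphometry.pointwise_stats(np.ones((1, 10)))
        assert np.isnan(stats.p_value).all()
        assert not stats.significant.any()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(morphometry.MeasurementError):
            morphometry.group_stats(np.zeros((3, 10)), np.zeros((3, 12)), np.zeros((3, 10)))


def test_rigid_motion_equivariance():
    """Moving both contours rigidly leaves all measurements unchanged."""
    peri = circle_contour(150.0, 90, surface=PERIOSTEAL)
    endo = circle_contour(100.0, 90, center=(15.0, -5.0), surface=ENDOSTEAL)
    adapted = peri.with_xy(peri.xy * 1.04)
    d0 = morphometry.surface_adaptation(adapted, peri)
    th0 = morphometry.hybrid_thickness(peri, endo)

    ang, shift = 0.7, np.array([123.0, -45.0])
    move = lambda c: c.with_xy(rotate_points(c.xy, ang) + shift)  # noqa: E731
    d1 = morphometry.surface_adaptation(move(adapted), move(peri))
    th1 = morphometry.hybrid_thickness(move(peri), move(endo))
    np.testing.assert_allclose(d1, d0, atol=1e-9)
    np.testing.assert_allclose(th1, th0, atol=1e-9)
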