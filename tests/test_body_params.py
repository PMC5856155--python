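import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from bovimetry.body_params import (
    BodyParameters, ImplausibleValueWarning, InconsistentGeometryError,
    aggregate_repeats, back_slope, body_depth, body_length, chest_girth,
    head_size, heights, hip_distance, ramanujan_perimeter,
)
from bovimetry.landmarks import Landmark


def lm(name, x, y, z):
    return Landmark(name, np.array([x, y, z], float))


class TestDistances:
    def test_hip_distance_floor_projected(self):
        d = hip_distance(lm("hip_left", -225, 0, 1400), lm("hip_right", 225, 0, 1400))
        assert d == 450.0
        # z difference must not enter
        d2 = hip_distance(lm("hip_left", -225, 0, 1400), lm("hip_right", 225, 0, 900))
        assert d2 == 450.0

    def test_coincident_hips_flagged(self):
        with pytest.warns(ImplausibleValueWarning):
            assert hip_distance(lm("a", 0, 0, 0), lm("b", 0, 0, 0)) == 0.0

    def test_body_length(self):
        assert body_length(lm("w", 1000, 0, 1300), lm("t", -500, 0, 1350)) == 1500.0

    def test_head_size_is_full_3d_distance(self):
        assert head_size(lm("l", 0, 60, 10), lm("r", 0, -60, 10)) == 120.0


class TestHeights:
    def test_datum_arithmetic(self):
        f, b, a = heights(lm("w", 0, 0, 1400), lm("hl", 0, 100, 1340),
                          lm("hr", 0, -100, 1360), datum=0.0)
        assert (f, b, a) == (1400.0, 1350.0, 1375.0)
        f2, b2, a2 = heights(lm("w", 0, 0, 1400), lm("hl", 0, 100, 1340),
                             lm("hr", 0, -100, 1360), datum=12.0)
        assert (f2, b2, a2) == (1388.0, 1338.0, 1363.0)


class TestBackSlope:
    def test_level_topline_is_zero(self):
        assert back_slope(1300.0, 1300.0, 1000.0) == 0.0

    def test_arctangent_value(self):
        assert back_slope(1400.0, 1300.0, 1000.0) == pytest.approx(5.7106, abs=1e-4)

    @given(st.floats(-200, 200), st.floats(100, 3000))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, diff, length):
        assert back_slope(1000.0 + diff, 1000.0, length) == pytest.approx(
            -back_slope(1000.0, 1000.0 + diff, length), abs=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            back_slope(1400.0, 1300.0, 0.0)


def ellipse_points(a, b, t0=0.0, t1=2 * np.pi, n=2000, center=(0.0, 500.0)):
    t = np.linspace(t0, t1, n)
    return np.column_stack([
        np.zeros(n), center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


def arc_length(a, b):
    val, _ = quad(lambda t: math.hypot(a * math.sin(t), b * math.cos(t)),
                  0.0, 2 * math.pi, limit=200)
    return val


class TestChestGirth:
    def test_full_cylinder_circumference(self):
        pts = ellipse_points(300.0, 300.0)
        g = chest_girth(pts, chest_x=0.0, slab_width=30.0)
        assert g.perimeter == pytest.approx(2 * np.pi * 300.0, rel=0.005)
        assert g.coverage > 0.95

    def test_partial_ellipse_matches_quadrature(self):
        """270-degree arc of a 350 x 250 ellipse: Ramanujan perimeter of the
        fit matches numerical arc-length integration within 1%."""
        pts = ellipse_points(350.0, 250.0, t0=0.0, t1=1.5 * np.pi)
        g = chest_girth(pts, chest_x=0.0, slab_width=30.0)
        assert g.perimeter == pytest.approx(arc_length(350.0, 250.0), rel=0.01)

    def test_low_coverage_warns(self):
        from bovimetry.body_params import LowCoverageWarning

        pts = ellipse_points(350.0, 250.0, t0=0.0, t1=0.6 * np.pi)
        with pytest.warns(LowCoverageWarning):
            chest_girth(pts, chest_x=0.0, slab_width=30.0)

    def test_empty_slab_rejected(self):
        pts = ellipse_points(300.0, 300.0)
        with pytest.raises(InconsistentGeometryError):
            chest_girth(pts, chest_x=500.0, slab_width=30.0)

    @given(st.floats(120.0, 400.0), st.floats(120.0, 400.0))
    @settings(max_examples=30, deadline=None)
    def test_ramanujan_matches_quadrature(self, a, b):
        assert ramanujan_perimeter(a, b) == pytest.approx(arc_length(a, b),
                                                          rel=1e-6)


class TestDepth:
    def test_difference(self):
        assert body_depth(1000.0, 600.0) == 400.0
        assert body_depth(1000.0, 0.0) == 1000.0

    def test_conservation_with_girth(self):
        pts = ellipse_points(140.0, 180.0, center=(0.0, 420.0))
        g = chest_girth(pts, chest_x=0.0)
        depth = body_depth(650.0, g.vertical_extent)
        assert depth + g.vertical_extent == pytest.approx(650.0, abs=1e-9)

    def test_extent_exceeding_height_rejected(self):
        with pytest.raises(InconsistentGeometryError):
            body_depth(500.0, 700.0)


class TestAggregate:
    def test_identical_repeats(self):
        reps = [BodyParameters(hip_distance=450.0, body_length=1500.0)
                for _ in range(10)]
        agg = aggregate_repeats(reps)
        assert agg.hip_distance == 450.0
        assert agg.dispersion["hip_distance"] == 0.0
        assert agg.n_repeats == 10

    def test_mean_and_sample_sd(self):
        reps = [BodyParameters(hip_distance=v) for v in (1.0, 2.0, 3.0)]
        agg = aggregate_repeats(reps)
        assert agg.hip_distance == pytest.approx(2.0)
        assert agg.dispersion["hip_distance"] == pytest.approx(1.0)

    def test_nan_parameters_skipped(self):
        reps = [BodyParameters(hip_distance=1.0),
                BodyParameters(hip_distance=float("nan"))]
        agg = aggregate_repeats(reps)
        assert agg.hip_distance == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_repeats([])
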