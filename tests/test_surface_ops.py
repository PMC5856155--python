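import numpy as np
import pytest

from bovimetry.render import generate_hemisphere, render_depth
from bovimetry.surface_ops import (
    DegenerateGeometryError, NothingAboveThresholdError, derivative_maps,
    fit_plane, level_frame_to_floor, level_to_plane, register_views,
    segment_body,
)


def grid_points(f, span=50.0, n=30):
    x, y = np.meshgrid(np.linspace(-span, span, n), np.linspace(-span, span, n))
    return np.column_stack([x.ravel(), y.ravel(), f(x, y).ravel()])


class TestFitPlane:
    def test_horizontal_plane(self):
        p = fit_plane(grid_points(lambda x, y: 0.0 * x))
        assert np.allclose(p.normal, [0, 0, 1], atol=1e-12)
        assert p.offset == pytest.approx(0.0, abs=1e-12)

    def test_inclined_plane_slope(self):
        p = fit_plane(grid_points(lambda x, y: 0.1 * x + 5.0))
        assert p.slope_deg == pytest.approx(np.degrees(np.arctan(0.1)), abs=1e-9)

    def test_noisy_plane_normal_unbiased(self):
        normals = []
        for s in range(30):
            rng = np.random.default_rng(s)
            pts = grid_points(lambda x, y: 0.1 * x)
            pts[:, 2] += rng.normal(0, 1.0, len(pts))
            normals.append(fit_plane(pts).normal)
        mean_n = np.mean(normals, axis=0)
        mean_n /= np.linalg.norm(mean_n)
        truth = np.array([-0.1, 0, 1.0]) / np.sqrt(1.01)
        assert np.allclose(mean_n, truth, atol=3e-3)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(10.0), np.arange(10.0), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            fit_plane(line)


class TestLeveling:
    def test_identity_for_level_input(self):
        pts = grid_points(lambda x, y: 0.0 * x)
        p = fit_plane(pts)
        out = level_to_plane(pts, p)
        assert np.allclose(out, pts, atol=1e-12)

    def test_rigid_distances_preserved(self):
        pts = grid_points(lambda x, y: 0.17 * x - 0.05 * y + 12.0)
        out = level_to_plane(pts, fit_plane(pts))
        d_in = np.linalg.norm(pts[1:] - pts[:-1], axis=1)
        d_out = np.linalg.norm(out[1:] - out[:-1], axis=1)
        assert np.allclose(d_in, d_out, atol=1e-9)
        assert np.abs(out[:, 2]).max() < 1e-9

    def test_floor_leveling_of_rendered_frame(self, phantom, sensor_1m):
        frame = render_depth(phantom, "top", sensor_1m, seed=4)
        leveled, plane = level_frame_to_floor(frame)
        z = leveled.heights()
        floor = np.isfinite(z) & (z < 50.0)
        rms = np.sqrt(np.mean(z[floor] ** 2))
        assert rms <= 2.5 * sensor_1m.bgn_sd


class TestSegmentation:
    def test_threshold_above_everything_errors(self, rendered_views):
        with pytest.raises(NothingAboveThresholdError):
            segment_body(rendered_views["top"], 5000.0)

    def test_largest_component_retained(self, phantom, rendered_views):
        """Torso and head are disjoint blobs from above; only the larger
        (torso) survives."""
        mask = segment_body(rendered_views["top"], 300.0)
        xg, _ = rendered_views["top"].pixel_grid()
        xw = xg + rendered_views["top"].pose[0, 3]
        assert xw[mask].max() < phantom.a + 1.0  # head blob excluded

    def test_footprint_area_close_to_torso(self, phantom, rendered_views):
        mask = segment_body(rendered_views["top"], 300.0)
        pitch = rendered_views["top"].sensor.lateral_pitch
        area = mask.sum() * pitch ** 2
        # analytic footprint: integral of the torso width profile
        xs = np.linspace(-phantom.a, phantom.a, 2001)
        width = 2 * phantom.b * phantom.section_scale(xs)
        analytic = np.trapezoid(width, xs)
        assert area == pytest.approx(analytic, rel=0.05)


class TestDerivativeMaps:
    def test_linear_field_has_constant_gradient_zero_curvature(self, sensor_1m_clean):
        from bovimetry.render import generate_flat_plane

        frame = generate_flat_plane(0.0, tilt_deg=np.degrees(np.arctan(0.2)),
                                    pitch=1.0)
        maps = derivative_maps(frame, smoothing_scale=0.0)
        sel = maps.mask
        assert np.allclose(maps.gradient_magnitude[sel], 0.2, atol=1e-6)
        assert np.abs(maps.mean_curvature[sel]).max() < 1e-6

    def test_sphere_apex_mean_curvature(self):
        frame = generate_hemisphere(150.0, pitch=1.0)
        maps = derivative_maps(frame, smoothing_scale=0.0)
        r, c = frame.values.shape[0] // 2, frame.values.shape[1] // 2
        assert maps.mean_curvature[r, c] == pytest.approx(-1.0 / 150.0, rel=0.05)
        assert maps.gradient_magnitude[r, c] < 0.01

    def test_gradient_magnitude_consistency(self, rendered_views):
        maps = derivative_maps(rendered_views["top"], smoothing_scale=5.0)
        sel = maps.mask
        gm = np.hypot(maps.gradient_x, maps.gradient_y)
        assert np.allclose(maps.gradient_magnitude[sel], gm[sel], rtol=1e-12)

    def test_shift_equivariance(self, phantom, sensor_1m_clean):
        """Translating the camera aim in-plane shifts detections with it."""
        a = render_depth(phantom, "top", sensor_1m_clean, seed=0)
        b = render_depth(phantom, "top", sensor_1m_clean, seed=0,
                         target=np.array([phantom.truth.x_withers % a.sensor.lateral_pitch - 30.0,
                                          0.0, phantom.zc + phantom.c]))
        ma = derivative_maps(a, smoothing_scale=5.0)
        mb = derivative_maps(b, smoothing_scale=5.0)
        # compare curvature at the same world point (withers apex)
        t = phantom.truth

        def curv_at(m, x, y):
            d2 = np.where(m.mask, (m.x - x) ** 2 + (m.y - y) ** 2, np.inf)
            return m.mean_curvature[np.unravel_index(np.argmin(d2), d2.shape)]

        ca = curv_at(ma, t.x_withers, 0.0)
        cb = curv_at(mb, t.x_withers, 0.0)
        assert cb == pytest.approx(ca, rel=0.05)


class TestRegistration:
    def test_single_cloud_pass_through(self):
        pts = np.random.default_rng(0).uniform(-10, 10, size=(100, 3))
        out = register_views([pts], refine=True)
        assert np.allclose(out, pts)

    def test_exact_poses_refinement_near_identity(self, phantom, sensor_1m_clean):
        """Two overlapping captures already in the world frame: refinement
        stays near the identity (rotation well below a degree)."""
        pitch = sensor_1m_clean.lateral_pitch
        a = render_depth(phantom, "top", sensor_1m_clean, seed=0).to_points()
        b = render_depth(phantom, "top", sensor_1m_clean, seed=0,
                         target=np.array([40 * pitch, 0.0, phantom.zc + phantom.c])
                         ).to_points()
        from bovimetry.surface_ops import icp_refine
        M = icp_refine(b, a, cutoff=5.0, max_points=4000)
        # rotation below 0.1 degree
        assert np.linalg.norm(M[:3, :3] - np.eye(3)) < np.radians(0.1) * np.sqrt(2)
        assert np.linalg.norm(M[:3, 3]) < 1.0

    def test_perturbed_pose_recovery(self, phantom, sensor_1m_clean):
        """A 2-degree / 20 mm mis-posed overlapping capture is pulled back
        onto the reference by trimmed ICP."""
        a = render_depth(phantom, "top", sensor_1m_clean, seed=0).to_points()
        b = render_depth(phantom, "top", sensor_1m_clean, seed=0,
                         target=np.array([50.0, 0.0, phantom.zc + phantom.c])
                         ).to_points()
        th = np.radians(2.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        b_bad = b @ R.T + [15.0, -10.0, 8.0]
        merged = register_views([a, b_bad], refine=True, max_points=4000,
                                max_iterations=200, cutoff=5.0)
        recovered = merged[len(a):]
        rms = np.sqrt(np.mean(np.sum((recovered - b) ** 2, axis=1)))
        rms_bad = np.sqrt(np.mean(np.sum((b_bad - b) ** 2, axis=1)))
        assert rms < 0.2 * rms_bad

    def test_voxel_dedup_reduces_duplicates(self):
        pts = np.random.default_rng(1).uniform(0, 10, size=(500, 3))
        doubled = np.vstack([pts, pts + 1e-4])
        out = register_views([doubled], refine=False, voxel=1.0)
        assert len(out) < len(doubled) / 1.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            register_views([])
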