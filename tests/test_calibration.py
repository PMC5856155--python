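import numpy as np
import pytest

from bovimetry.calibration import (
    CorrectionModel, UnreliableEstimateWarning, apply_correction,
    calibrate_sensor, derive_correction, estimate_bgn, fit_sphere,
    measure_hemisphere,
)
from bovimetry.render import generate_flat_plane, generate_hemisphere
from bovimetry.sensor import DepthFrame, SensorModel, camera_pose
from bovimetry.surface_ops import DegenerateGeometryError

from conftest import sphere_cloud


class TestFitSphere:
    def test_exact_points(self):
        fit = fit_sphere(sphere_cloud(100.0, 500))
        assert fit.radius == pytest.approx(100.0, abs=1e-6)
        assert fit.rms_residual < 1e-9

    def test_translation_equivariance(self):
        shift = np.array([50.0, -20.0, 7.0])
        base = fit_sphere(sphere_cloud(100.0, 500))
        moved = fit_sphere(sphere_cloud(100.0, 500) + shift)
        assert moved.radius == pytest.approx(base.radius, abs=1e-9)
        assert np.allclose(moved.center - base.center, shift, atol=1e-9)

    def test_noisy_monte_carlo_unbiased(self):
        """Mean fitted radius over seeds within 3 SE of the truth."""
        radii = [fit_sphere(sphere_cloud(100.0, 400, seed=s, noise_sd=1.0)).radius
                 for s in range(30)]
        se = np.std(radii, ddof=1) / np.sqrt(len(radii))
        assert abs(np.mean(radii) - 100.0) < 3 * max(se, 0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(np.random.default_rng(0).normal(size=(50, 3)) * [1, 1, 0])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(np.zeros((3, 3)))


class TestCorrection:
    nominals = [50.0, 100.0, 150.0, 200.0, 250.0]

    def test_identity_when_measured_equals_nominal(self):
        m = derive_correction(self.nominals, self.nominals)
        assert m.vertical_scale == pytest.approx(1.0, abs=1e-9)
        assert m.vertical_offset == pytest.approx(0.0, abs=1e-9)

    def test_pure_scale_distortion(self):
        m = derive_correction([1.02 * r for r in self.nominals], self.nominals)
        assert m.vertical_scale == pytest.approx(1 / 1.02, abs=1e-9)
        assert m.vertical_offset == pytest.approx(0.0, abs=1e-7)

    def test_affine_distortion_inverted(self):
        m = derive_correction([0.98 * r + 2.0 for r in self.nominals], self.nominals)
        assert m.vertical_scale == pytest.approx(1 / 0.98, abs=1e-9)
        assert m.vertical_offset == pytest.approx(-2.0 / 0.98, abs=1e-7)

    def test_single_radius_insufficient(self):
        with pytest.raises(DegenerateGeometryError):
            derive_correction([100.0, 100.0], [100.0, 100.0])

    def test_apply_identity_is_noop(self, sensor_1m):
        shape = (sensor_1m.rows, sensor_1m.columns)
        frame = DepthFrame(np.full(shape, 900.0), np.zeros(shape, bool), sensor_1m)
        out = apply_correction(frame, CorrectionModel.identity())
        assert np.array_equal(out.values, frame.values)

    def test_apply_scales_about_working_distance(self, sensor_1m):
        shape = (sensor_1m.rows, sensor_1m.columns)
        frame = DepthFrame(np.full(shape, sensor_1m.working_distance + 100.0),
                           np.zeros(shape, bool), sensor_1m)
        out = apply_correction(frame, CorrectionModel(scale=(1, 0.5), offset=(0, 3.0)))
        assert np.allclose(out.values, sensor_1m.working_distance + 50.0 + 3.0)

    def test_round_trip_restores_nominals_noiseless(self):
        """Substitution calibration on distorted noiseless hemispheres restores
        the nominal radii to <= 0.1%."""
        sensor = SensorModel.at_distance(1000).noiseless()
        sensor = SensorModel(
            working_distance=1000, lateral_range_h=730, lateral_range_v=550,
            vertical_resolution=0.0, bgn_sd=0.0, nonlinearity=0.005,
        )
        model = calibrate_sensor(sensor, seed=0, n_repeats=1)
        for nominal, fitted in model.provenance:
            corrected = model.vertical_scale * fitted + model.vertical_offset
            assert abs(corrected - nominal) / nominal < 1e-3


class TestEstimateBgn:
    def test_noiseless_plane_is_zero(self):
        frame = generate_flat_plane(0.0, pitch=1.0)
        assert estimate_bgn(frame) < 1e-9

    def test_recovers_injected_roughness(self):
        """Mean estimate over seeds within 10% of the injected 0.3 mm RMS."""
        vals = [estimate_bgn(generate_flat_plane(0.3, seed=s)) for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.3, rel=0.1)

    def test_invariant_to_tilt_and_offset(self):
        flat = estimate_bgn(generate_flat_plane(0.3, seed=1))
        tilted = estimate_bgn(generate_flat_plane(0.3, tilt_deg=10.0, seed=1))
        assert tilted == pytest.approx(flat, rel=0.05)
        frame = generate_flat_plane(0.3, seed=1)
        frame.values = frame.values + 123.0
        assert estimate_bgn(frame) == pytest.approx(flat, rel=1e-6)

    def test_table_noise_level_recovered(self):
        """A flat target rendered with the 1 m sensor noise (3.2 mm) yields a
        BGN estimate near 3.2 mm."""
        vals = []
        for s in range(10):
            frame = generate_flat_plane(0.0, pitch=1.14, seed=s)
            rng = np.random.default_rng(1000 + s)
            frame.values = frame.values + rng.normal(0, 3.2, frame.values.shape)
            vals.append(estimate_bgn(frame))
        assert np.mean(vals) == pytest.approx(3.2, rel=0.05)

    def test_mostly_void_frame_warns(self, sensor_1m):
        shape = (sensor_1m.rows, sensor_1m.columns)
        values = np.full(shape, 1000.0)
        void = np.ones(shape, bool)
        void[:100, :100] = False
        values[void] = np.nan
        frame = DepthFrame(values, void, sensor_1m)
        with pytest.warns(UnreliableEstimateWarning):
            estimate_bgn(frame)


def test_full_calibration_reduces_residuals(sensor_1m):
    """Calibrating the noisy, distorted 1 m sensor yields corrected radii
    within 0.5 mm of the nominals."""
    model = calibrate_sensor(sensor_1m, seed=3)
    for nominal, fitted in model.provenance:
        corrected = model.vertical_scale * fitted + model.vertical_offset
        assert abs(corrected - nominal) < 0.5
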