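"""Render analytic surfaces into depth frames through the virtual sensor.

The camera model is orthographic-with-pitch: pixels sample the scene on a
regular lateral grid whose spacing is the sensor's distance-dependent
lateral pitch.  The physical measurement chain is applied in order:

1. geometric range along the view axis (nearest surface wins, which also
   realises self-shadowing between components);
2. slope dropout: pixels whose local surface inclination to the viewing ray
   exceeds the maximum detectable slope (45 degrees) become void;
3. length non-linearity: ``r' = r * (1 + nl * (r - d0) / d0)`` with ``d0``
   the working distance;
4. additive Gaussian background noise of the sensor's BGN standard deviation;
5. vertical quantization to the sensor's vertical resolution step.

Reference targets (hemispheres on a plane, textured flat planes) used for
substitution calibration and background-noise estimation are generated here
as well.
"""

from __future__ import annotations

import numpy as np

from .phantom import CowPhantom
from .sensor import SensorModel, DepthFrame, camera_pose, VIEWS

__all__ = [
    "render_depth",
    "generate_hemisphere",
    "generate_flat_plane",
    "default_view_target",
    "Posture",
]


from dataclasses import dataclass


@dataclass(frozen=True)
class Posture:
    """Stance of the animal at capture time, relative to the neutral pose.

    A standing animal flexes and shifts between captures: ``height_offset``
    raises/lowers the trunk (legs flex; hooves stay on the floor) and
    ``pitch_deg`` tilts the topline about the trunk centre (head-down
    grazing versus head-up posture).  The phantom's ground truth refers to
    the neutral pose, so posture variation propagates into the measurements
    exactly as live-animal posture does.
    """

    pitch_deg: float = 0.0
    height_offset: float = 0.0

    @property
    def slope(self) -> float:
        return float(np.tan(np.radians(self.pitch_deg)))


def default_view_target(phantom: CowPhantom, view: str) -> np.ndarray:
    """Where the operator aims each capture: the relevant body portion."""
    if view == "top":
        x_mid = 0.5 * (phantom.tail_x + phantom.withers_x)
        return np.array([x_mid, 0.0, phantom.zc + phantom.c])
    if view in ("left", "right"):
        return np.array([0.0, 0.0, phantom.zc])
    if view == "front":
        return phantom.head_center()
    raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")


def _leg_chord(phantom, coord, center):
    with np.errstate(invalid="ignore"):
        d2 = phantom.leg_radius ** 2 - (coord - center) ** 2
        return np.where(d2 > 0, np.sqrt(np.maximum(d2, 0.0)), np.nan)


def _phantom_geometric_range(phantom: CowPhantom, view: str, pose, xg, yg,
                             posture: Posture | None = None):
    """Geometric range (mm) per pixel; NaN where no surface is hit.

    Posture (small-angle trunk pitch about the body centre plus a trunk
    height offset) shears the body surfaces; the floor and the hoof contact
    stay fixed.
    """
    R, t = pose[:3, :3], pose[:3, 3]
    slope = posture.slope if posture else 0.0
    dz = posture.height_offset if posture else 0.0
    if view == "top":
        x = xg + t[0]
        y = yg + t[1]
        h = np.fmax(phantom.torso_top(x, y), phantom.head_top(x, y))
        h = h + dz + slope * x
        h = np.where(np.isnan(h), 0.0, np.fmax(h, 0.0))  # floor plane at z = 0
        return t[2] - h
    if view in ("left", "right"):
        x = (xg if view == "left" else -xg) + t[0]
        z = yg + t[2]
        zb = z - dz - slope * x  # body-frame height
        surf = np.fmax(phantom.torso_halfwidth(x, zb), phantom.head_halfwidth(x, zb))
        zmask = (z >= 0.0) & (z <= phantom.zc)
        for (xl, yl) in phantom.leg_positions():
            chord = _leg_chord(phantom, x, xl)
            leg_y = np.where(zmask, abs(yl) + chord, np.nan)
            surf = np.fmax(surf, leg_y)
        return abs(t[1]) - surf  # |camera plane offset| minus lateral extent
    if view == "front":
        y = xg + t[1]
        z = yg + t[2]
        zb = z - dz - slope * float(phantom.head_center()[0])
        surf = np.fmax(phantom.head_front(y, zb), phantom.torso_nose(y, z - dz - slope * phantom.a))
        zmask = (z >= 0.0) & (z <= phantom.zc)
        for (xl, yl) in phantom.leg_positions():
            chord = _leg_chord(phantom, y, yl)
            leg_x = np.where(zmask, xl + chord, np.nan)
            surf = np.fmax(surf, leg_x)
        return t[0] - surf
    raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")


def _finalize(r_geo, sensor: SensorModel, view: str, pose, rng) -> DepthFrame:
    """Apply slope dropout, distortion, noise and quantization to a range map."""
    pitch = sensor.lateral_pitch
    slope_limit = np.tan(np.radians(sensor.max_slope_deg))
    with np.errstate(invalid="ignore"):
        gy, gx = np.gradient(r_geo, pitch)
        steep = np.hypot(gx, gy) > slope_limit
    void = ~np.isfinite(r_geo) | steep | ~np.isfinite(np.hypot(gx, gy))

    r = r_geo.copy()
    d0 = sensor.working_distance
    if sensor.nonlinearity != 0.0:
        r = r * (1.0 + sensor.nonlinearity * (r - d0) / d0)
    if sensor.bgn_sd > 0.0:
        r = r + rng.normal(0.0, sensor.bgn_sd, size=r.shape)
    if sensor.vertical_resolution > 0.0:
        step = sensor.vertical_resolution
        r = np.round(r / step) * step
    r = np.where(void, np.nan, r)
    return DepthFrame(values=r, void_mask=void, sensor=sensor, view=view, pose=pose)


def render_depth(phantom: CowPhantom, view: str, sensor: SensorModel,
                 seed: int = 0, target=None,
                 posture: Posture | None = None) -> DepthFrame:
    """Ray-cast the phantom into a depth frame from one canonical viewpoint.

    ``target`` is the world point the camera is aimed at (defaults to the
    body portion relevant for the view); the camera reference plane sits at
    the sensor working distance from it.  ``posture`` perturbs the animal's
    stance relative to the neutral pose.
    """
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    if not (400.0 <= sensor.working_distance <= 2000.0):
        raise ValueError("working distance must lie within 400-2000 mm")
    if target is None:
        target = default_view_target(phantom, view)
    pose = camera_pose(view, sensor, np.asarray(target, float))
    frame_stub = DepthFrame(
        np.zeros((sensor.rows, sensor.columns)),
        np.zeros((sensor.rows, sensor.columns), bool), sensor, view, pose,
    )
    xg, yg = frame_stub.pixel_grid()
    r_geo = _phantom_geometric_range(phantom, view, pose, xg, yg, posture)
    rng = np.random.default_rng(seed)
    return _finalize(r_geo, sensor, view, pose, rng)


def _reference_sensor(pitch: float, noise_sd: float, working_distance: float,
                      vertical_resolution: float, nonlinearity: float) -> SensorModel:
    return SensorModel(
        working_distance=working_distance,
        lateral_range_h=pitch * 640,
        lateral_range_v=pitch * 480,
        vertical_resolution=vertical_resolution,
        bgn_sd=noise_sd,
        nonlinearity=nonlinearity,
    )


def generate_hemisphere(radius: float, pitch: float, noise_sd: float = 0.0,
                        seed: int = 0, working_distance: float = 1000.0,
                        vertical_resolution: float = 0.0,
                        nonlinearity: float = 0.0) -> DepthFrame:
    """Top-view depth frame of a reference hemisphere resting on a plane.

    Mimics the polystyrene calibration artefacts (nominal radii 50-250 mm).
    With ``noise_sd = 0`` and no quantization the apex height above the plane
    equals the radius exactly.
    """
    if radius <= 0 or pitch <= 0:
        raise ValueError("radius and pitch must be positive")
    sensor = _reference_sensor(pitch, noise_sd, working_distance,
                               vertical_resolution, nonlinearity)
    pose = camera_pose("top", sensor, np.array([0.0, 0.0, radius]))
    stub = DepthFrame(np.zeros((sensor.rows, sensor.columns)),
                      np.zeros((sensor.rows, sensor.columns), bool), sensor, "top", pose)
    xg, yg = stub.pixel_grid()
    with np.errstate(invalid="ignore"):
        h2 = radius ** 2 - xg ** 2 - yg ** 2
        h = np.where(h2 > 0, np.sqrt(np.maximum(h2, 0.0)), 0.0)
    r_geo = pose[2, 3] - h
    rng = np.random.default_rng(seed)
    return _finalize(r_geo, sensor, "top", pose, rng)


def generate_flat_plane(rms_roughness: float = 0.0, tilt_deg: float = 0.0,
                        pitch: float = 1.14, seed: int = 0,
                        working_distance: float = 1000.0,
                        vertical_resolution: float = 0.0) -> DepthFrame:
    """Depth frame of a flat reference plane with Gaussian surface texture.

    The texture RMS models the reference plane's roughness (< 0.3 mm for the
    physical artefact); it is part of the surface, not sensor noise.  Tilting
    the plane beyond the maximum detectable slope voids every pixel.
    """
    if rms_roughness < 0:
        raise ValueError("rms_roughness must be non-negative")
    sensor = _reference_sensor(pitch, 0.0, working_distance, vertical_resolution, 0.0)
    pose = camera_pose("top", sensor, np.array([0.0, 0.0, 0.0]))
    stub = DepthFrame(np.zeros((sensor.rows, sensor.columns)),
                      np.zeros((sensor.rows, sensor.columns), bool), sensor, "top", pose)
    xg, yg = stub.pixel_grid()
    rng = np.random.default_rng(seed)
    h = xg * np.tan(np.radians(tilt_deg))
    if rms_roughness > 0:
        h = h + rng.normal(0.0, rms_roughness, size=h.shape)
    r_geo = pose[2, 3] - h
    return _finalize(r_geo, sensor, "top", pose, rng)
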