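"""Virtual structured-light depth camera description and its native data product.

The sensor is modelled after a consumer RGB-D triangulation camera with a
640 x 480 IR imager.  Its scanning performance depends on the working
distance: the lateral footprint, the lateral pitch (mm per pixel), the
vertical quantization step and the background noise (BGN, the RMS roughness
measured on a flat reference) all degrade as the target moves away.  The
reference performance table used for defaults is::

    distance (mm)   lateral range (mm)   pitch (mm)   vert. res. (mm)   BGN (mm)
    400             415 x 310            0.65         0.7               1.1
    1000            730 x 550            1.14         2.0               3.2
    2000            1250 x 950           1.95         4.0               5.5

Surfaces inclined more than 45 degrees to the viewing ray return no signal
and are flagged void.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

VIEWS = ("left", "right", "top", "front")

#: distance -> (lateral_range_h, lateral_range_v, vertical_resolution, bgn_sd)
PERFORMANCE_TABLE = {
    400.0: (415.0, 310.0, 0.7, 1.1),
    1000.0: (730.0, 550.0, 2.0, 3.2),
    2000.0: (1250.0, 950.0, 4.0, 5.5),
}

SENSOR_COLUMNS = 640
SENSOR_ROWS = 480
MAX_SLOPE_DEG = 45.0
DEFAULT_NONLINEARITY = 0.005  # fractional length distortion per unit relative range


def _interp_performance(distance: float) -> tuple[float, float, float, float]:
    """Linear interpolation of the performance table between tabulated distances."""
    ds = np.array(sorted(PERFORMANCE_TABLE))
    if not (ds[0] <= distance <= ds[-1]):
        raise ValueError(
            f"working distance {distance} mm outside supported range "
            f"[{ds[0]:.0f}, {ds[-1]:.0f}] mm"
        )
    cols = np.array([PERFORMANCE_TABLE[d] for d in ds])
    return tuple(float(np.interp(distance, ds, cols[:, j])) for j in range(4))


@dataclass(frozen=True)
class SensorModel:
    """Resolution, noise, dropout and distortion description of the depth camera.

    Parameters are in millimetres unless noted.  ``lateral_pitch`` is derived
    as ``lateral_range_h / columns`` and is the grid spacing of the
    orthographic sampling used by the renderer.
    """

    columns: int = SENSOR_COLUMNS
    rows: int = SENSOR_ROWS
    working_distance: float = 1000.0
    lateral_range_h: float = 730.0
    lateral_range_v: float = 550.0
    vertical_resolution: float = 2.0
    bgn_sd: float = 3.2
    max_slope_deg: float = MAX_SLOPE_DEG
    nonlinearity: float = DEFAULT_NONLINEARITY
    correction: Optional[object] = None  # CorrectionModel; identity when None

    def __post_init__(self):
        if self.columns <= 0 or self.rows <= 0:
            raise ValueError("pixel counts must be positive")
        if self.lateral_range_h <= 0 or self.lateral_range_v <= 0:
            raise ValueError("lateral ranges must be positive")
        if self.vertical_resolution < 0 or self.bgn_sd < 0:
            raise ValueError("vertical_resolution and bgn_sd must be non-negative")

    @property
    def lateral_pitch(self) -> float:
        """Lateral sampling pitch in mm/pixel."""
        return self.lateral_range_h / self.columns

    @classmethod
    def at_distance(cls, working_distance: float, **overrides) -> "SensorModel":
        """Sensor configured for a working distance in [400, 2000] mm.

        Performance figures are taken from the reference table, linearly
        interpolated between the tabulated distances.
        """
        rh, rv, vres, bgn = _interp_performance(float(working_distance))
        params = dict(
            working_distance=float(working_distance),
            lateral_range_h=rh,
            lateral_range_v=rv,
            vertical_resolution=vres,
            bgn_sd=bgn,
        )
        params.update(overrides)
        return cls(**params)

    def noiseless(self) -> "SensorModel":
        """Copy with noise, quantization and distortion switched off."""
        return replace(self, bgn_sd=0.0, vertical_resolution=0.0, nonlinearity=0.0)


@dataclass
class DepthFrame:
    """Rectangular grid of range values (mm) with a void mask.

    ``values[r, c]`` is the range from the camera reference plane to the
    surface along the ray of pixel ``(r, c)``; entries where ``void_mask`` is
    True carry no signal (NaN).  ``pose`` is the 4x4 rigid transform mapping
    camera coordinates ``(x_cam, y_cam, range)`` to the world frame (floor at
    z = 0, +z up).
    """

    values: np.ndarray
    void_mask: np.ndarray
    sensor: SensorModel
    view: str = "top"
    pose: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.void_mask = np.asarray(self.void_mask, dtype=bool)
        if self.values.shape != self.void_mask.shape:
            raise ValueError("values and void_mask shapes differ")
        if self.values.shape != (self.sensor.rows, self.sensor.columns):
            raise ValueError(
                f"grid shape {self.values.shape} does not match sensor "
                f"({self.sensor.rows}, {self.sensor.columns})"
            )
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        if not np.all(np.isfinite(self.values[~self.void_mask])):
            raise ValueError("non-finite range values outside the void mask")

    @property
    def valid_fraction(self) -> float:
        return float(1.0 - self.void_mask.mean())

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Camera-frame lateral coordinates (x_cam, y_cam) of every pixel, mm.

        x_cam runs along columns, y_cam along rows (row 0 at +y_cam); both are
        centred on the optical axis.
        """
        p = self.sensor.lateral_pitch
        cols = (np.arange(self.sensor.columns) - (self.sensor.columns - 1) / 2.0) * p
        rows = ((self.sensor.rows - 1) / 2.0 - np.arange(self.sensor.rows)) * p
        return np.meshgrid(cols, rows)

    def to_points(self, world: bool = True) -> np.ndarray:
        """Valid pixels as an (N, 3) point cloud, camera or world frame, mm."""
        xg, yg = self.pixel_grid()
        ok = ~self.void_mask
        pts = np.column_stack([xg[ok], yg[ok], self.values[ok]])
        if not world:
            return pts
        return pts @ self.pose[:3, :3].T + self.pose[:3, 3]

    def heights(self) -> np.ndarray:
        """World-frame z (height above floor) per pixel; NaN where void."""
        xg, yg = self.pixel_grid()
        R, t = self.pose[:3, :3], self.pose[:3, 3]
        z = xg * R[2, 0] + yg * R[2, 1] + self.values * R[2, 2] + t[2]
        z = np.where(self.void_mask, np.nan, z)
        return z

    def copy(self) -> "DepthFrame":
        return DepthFrame(
            self.values.copy(), self.void_mask.copy(), self.sensor, self.view,
            self.pose.copy(),
        )


def camera_pose(view: str, sensor: SensorModel, target: np.ndarray) -> np.ndarray:
    """Pose of the canonical orthographic camera for ``view`` aimed at ``target``.

    The camera reference plane sits ``sensor.working_distance`` mm from the
    target point, with the optical axis along -z (top), -y/+y (left/right
    flank) or -x (front).  Returns the 4x4 camera-to-world transform for
    pixel coordinates ``(x_cam, y_cam, range)``.
    """
    d = sensor.working_distance
    t = np.asarray(target, dtype=float)
    T = np.eye(4)
    if view == "top":
        # x_cam -> +x, y_cam -> +y, range -> -z from plane z = t_z + d
        T[:3, :3] = np.array([[1, 0, 0], [0, 1, 0], [0, 0, -1.0]])
        T[:3, 3] = [0.0, 0.0, t[2] + d]
        T[0, 3] = t[0]
        T[1, 3] = t[1]
    elif view == "left":
        # camera on +y side looking toward -y; x_cam -> +x, y_cam -> +z
        T[:3, :3] = np.array([[1, 0, 0], [0, 0, -1.0], [0, 1, 0]])
        T[:3, 3] = [t[0], t[1] + d, t[2]]
    elif view == "right":
        # camera on -y side looking toward +y; x_cam -> -x (mirror), y_cam -> +z
        T[:3, :3] = np.array([[-1.0, 0, 0], [0, 0, 1.0], [0, 1, 0]])
        T[:3, 3] = [t[0], t[1] - d, t[2]]
    elif view == "front":
        # camera ahead of the muzzle looking toward -x; x_cam -> +y, y_cam -> +z
        T[:3, :3] = np.array([[0, 0, -1.0], [1, 0, 0], [0, 1, 0]])
        T[:3, 3] = [t[0] + d, t[1], t[2]]
    else:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    return T
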