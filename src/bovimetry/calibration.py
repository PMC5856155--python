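"""Substitution calibration on hemispherical references and noise estimation.

The virtual sensor (like the physical one) is calibrated by measuring
reference artefacts of known size: five polystyrene hemispheres with
nominal radii 50-250 mm.  A least-squares sphere is fitted to each
measured cap, and a linear (scale + offset) correction mapping fitted to
nominal radii is derived and subsequently applied to the vertical values of
every frame.  Background noise (BGN) is quantified on a flat reference as
the RMS roughness of the signal after total-least-squares plane removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .sensor import DepthFrame
from .surface_ops import DegenerateGeometryError, fit_plane

__all__ = [
    "SphereFit", "CorrectionModel", "fit_sphere", "derive_correction",
    "apply_correction", "estimate_bgn", "measure_hemisphere",
    "calibrate_sensor", "UnreliableEstimateWarning",
]


class UnreliableEstimateWarning(UserWarning):
    pass


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: centre (mm), radius (mm), RMS surface residual."""

    center: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")


@dataclass(frozen=True)
class CorrectionModel:
    """Linear per-axis correction ``value' = scale * value + offset``.

    ``scale``/``offset`` are (lateral, vertical) pairs; the substitution
    calibration on hemisphere radii constrains the vertical axis, the
    lateral axis defaults to identity.  ``provenance`` records the
    (nominal, fitted) radius pairs the model was fitted on.
    """

    scale: tuple[float, float] = (1.0, 1.0)
    offset: tuple[float, float] = (0.0, 0.0)
    provenance: tuple = field(default_factory=tuple)

    @classmethod
    def identity(cls) -> "CorrectionModel":
        return cls()

    @property
    def vertical_scale(self) -> float:
        return self.scale[1]

    @property
    def vertical_offset(self) -> float:
        return self.offset[1]


def fit_sphere(points) -> SphereFit:
    """Least-squares sphere through a point cloud.

    Algebraic linearisation (Coope) followed by Gauss-Newton refinement of
    the geometric point-to-surface residuals; ``rms_residual`` is the RMS of
    those distances.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise DegenerateGeometryError("sphere fit needs at least 4 points (N, 3)")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    bvec = (pts ** 2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, bvec, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise DegenerateGeometryError("degenerate (coplanar) points: sphere undetermined")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit collapsed")
    radius = float(np.sqrt(r2))

    def residuals(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    res = least_squares(residuals, np.r_[center, radius], method="lm",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    cx, cy, cz, r = res.x
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return SphereFit(center=np.array([cx, cy, cz]), radius=float(r), rms_residual=rms)


def derive_correction(fits, nominals) -> CorrectionModel:
    """Scale/offset mapping fitted hemisphere radii onto their nominals.

    Ordinary least squares of ``nominal = scale * fitted + offset`` over the
    reference set; with measured == nominal the identity model is recovered
    exactly.
    """
    fitted = np.array([f.radius if isinstance(f, SphereFit) else float(f) for f in fits])
    nominal = np.asarray(nominals, float)
    if len(fitted) != len(nominal):
        raise ValueError("fits and nominals must align")
    if len(np.unique(nominal)) < 2:
        raise DegenerateGeometryError(
            "need at least 2 distinct nominal radii to constrain scale and offset"
        )
    A = np.column_stack([fitted, np.ones_like(fitted)])
    (scale, offset), *_ = np.linalg.lstsq(A, nominal, rcond=None)
    return CorrectionModel(
        scale=(1.0, float(scale)), offset=(0.0, float(offset)),
        provenance=tuple(zip(nominal.tolist(), fitted.tolist())),
    )


def apply_correction(frame: DepthFrame, model: CorrectionModel) -> DepthFrame:
    """Map a frame's vertical (range) values through the correction model.

    The scale acts on deviations from the working distance so that the
    camera-to-target geometry is preserved while lengths are rescaled; the
    void mask is untouched.
    """
    out = frame.copy()
    d0 = frame.sensor.working_distance
    s, o = model.vertical_scale, model.vertical_offset
    with np.errstate(invalid="ignore"):
        out.values = d0 + s * (out.values - d0) + o
    out.values[frame.void_mask] = np.nan
    return out


def estimate_bgn(frame: DepthFrame) -> float:
    """Background noise: RMS roughness after best-fit plane removal.

    Fits a total-least-squares plane to the valid points and returns the RMS
    of the orthogonal residuals, making the estimate invariant to moderate
    plane tilt and to constant range offsets.  Warns when more than half of
    the frame is void.
    """
    void_frac = float(frame.void_mask.mean())
    if void_frac > 0.5:
        warnings.warn(
            f"{void_frac:.0%} of the frame is void; BGN estimate unreliable",
            UnreliableEstimateWarning,
        )
    pts = frame.to_points(world=False)
    if len(pts) < 3:
        raise DegenerateGeometryError("not enough valid pixels for BGN estimation")
    plane = fit_plane(pts)
    return float(np.sqrt(np.mean(plane.distance(pts) ** 2)))


def measure_hemisphere(frame: DepthFrame, nominal_radius: float | None = None,
                       ) -> SphereFit:
    """Sphere fit to the cap of a rendered reference hemisphere frame.

    The base plane is fitted on low pixels and removed; points standing
    clearly above it (beyond noise and quantization) enter the sphere fit.
    """
    z = frame.heights()
    ok = np.isfinite(z)
    zmax = np.nanmax(z)
    base = ok & (z < 0.15 * zmax)
    if base.sum() < 100:
        raise DegenerateGeometryError("no visible base plane around the hemisphere")
    xg, yg = frame.pixel_grid()
    R, t = frame.pose[:3, :3], frame.pose[:3, 3]

    def world(mask):
        pc = np.column_stack([xg[mask], yg[mask], frame.values[mask]])
        return pc @ R.T + t

    plane = fit_plane(world(base))
    clearance = 4.0 * frame.sensor.bgn_sd + 2.0 * frame.sensor.vertical_resolution + 2.0
    cap = ok & (z > clearance) & (z > 0.05 * zmax)
    if cap.sum() < 50:
        raise DegenerateGeometryError("hemisphere cap too small to fit")
    from .surface_ops import level_to_plane

    pts = level_to_plane(world(cap), plane)
    return fit_sphere(pts)


def calibrate_sensor(sensor, radii=(50.0, 100.0, 150.0, 200.0, 250.0),
                     seed: int = 0, n_repeats: int = 10) -> CorrectionModel:
    """Full substitution calibration of a virtual sensor configuration.

    Renders each reference hemisphere through the sensor's own noise,
    distortion and quantization chain, averages ``n_repeats`` captures
    pixelwise (mirroring the 10-measurement averaging of the physical
    procedure, which keeps the shallow-cap sphere fits unbiased), measures
    the caps and derives the linear correction model.
    """
    from .render import generate_hemisphere

    rng = np.random.default_rng(seed)
    fits, nominals = [], []
    for radius in radii:
        frames = [
            generate_hemisphere(
                radius, pitch=sensor.lateral_pitch,
                noise_sd=sensor.bgn_sd, seed=int(rng.integers(2 ** 31)),
                working_distance=sensor.working_distance,
                vertical_resolution=sensor.vertical_resolution,
                nonlinearity=sensor.nonlinearity,
            )
            for _ in range(n_repeats)
        ]
        mean = frames[0].copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-void pixels
            mean.values = np.nanmean(np.stack([f.values for f in frames]), axis=0)
        fits.append(measure_hemisphere(mean, radius))
        nominals.append(radius)
    return derive_correction(fits, nominals)
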