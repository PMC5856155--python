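"""Plane fitting/leveling, body segmentation, derivative maps and view merging.

These are the "data correction" and "image filtering" stages that sit
between raw depth frames and landmark extraction: a best-fit plane levels
each data set to the floor, the animal is segmented from the background,
and gradient/curvature maps expose the anatomical prominences that the
landmark rules key on.

Curvature sign convention: surfaces convex toward the sensor (bumps) have
negative mean curvature, so anatomical maxima are "null gradient, negative
curvature" pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .sensor import DepthFrame

__all__ = [
    "Plane", "DerivativeMaps", "fit_plane", "level_to_plane",
    "segment_body", "derivative_maps", "register_views",
    "DegenerateGeometryError", "NothingAboveThresholdError",
]


class DegenerateGeometryError(ValueError):
    """Input geometry does not constrain the requested fit."""


class NothingAboveThresholdError(ValueError):
    """Segmentation found no pixels above the height threshold."""


@dataclass(frozen=True)
class Plane:
    """Plane ``normal . p = offset`` with unit normal oriented toward +z."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset) / norm)

    def distance(self, points) -> np.ndarray:
        """Signed point-to-plane distances (positive on the normal side)."""
        return np.asarray(points, float) @ self.normal - self.offset

    @property
    def slope_deg(self) -> float:
        """Inclination of the plane to the horizontal, degrees."""
        return float(np.degrees(np.arccos(np.clip(abs(self.normal[2]), 0, 1))))


def fit_plane(points) -> Plane:
    """Total-least-squares plane through a point set.

    TLS (smallest singular direction of the centred cloud) makes the
    residuals orthogonal to the surface, which keeps roughness estimates
    unbiased under tilt.  The normal is oriented toward +z (the sensor side
    after leveling).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points (N, 3)")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane is undetermined")
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and normal[0] < 0):
        normal = -normal
    return Plane(normal=normal, offset=float(normal @ centroid))


def _leveling_transform(plane: Plane) -> np.ndarray:
    """Rigid 4x4 transform rotating ``plane`` onto z = 0."""
    n = plane.normal
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(n @ z)
    if s < 1e-15:
        R = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    M = np.eye(4)
    M[:3, :3] = R
    # point on the plane nearest the origin maps to z = 0
    M[:3, 3] = -R @ (n * plane.offset)
    M[2, 3] += 0.0
    return M


def level_to_plane(data, plane: Plane):
    """Rigidly move a cloud or frame so that ``plane`` coincides with z = 0.

    Distances are preserved exactly; for a :class:`DepthFrame` only the pose
    is updated (the range grid is untouched).
    """
    M = _leveling_transform(plane)
    if isinstance(data, DepthFrame):
        out = data.copy()
        out.pose = M @ data.pose
        return out
    pts = np.asarray(data, float)
    return pts @ M[:3, :3].T + M[:3, 3]


def level_frame_to_floor(frame: DepthFrame, floor_max_height: float = 100.0,
                         ) -> tuple[DepthFrame, Plane]:
    """Fit the floor on low pixels of a (near-leveled) frame and level to it.

    Convenience wrapper used by the pipeline on top views; raises
    :class:`DegenerateGeometryError` when fewer than 1% of pixels are floor.
    """
    z = frame.heights()
    low = np.isfinite(z) & (z < floor_max_height)
    if low.sum() < 0.01 * z.size:
        raise DegenerateGeometryError("no visible floor to level against")
    xg, yg = frame.pixel_grid()
    pts_cam = np.column_stack([xg[low], yg[low], frame.values[low]])
    pts = pts_cam @ frame.pose[:3, :3].T + frame.pose[:3, 3]
    plane = fit_plane(pts)
    return level_to_plane(frame, plane), plane


def segment_body(frame: DepthFrame, height_threshold: float,
                 include_void: bool = True) -> np.ndarray:
    """Boolean mask of the largest connected body component above the floor.

    Pixels are body candidates when their leveled height exceeds the
    threshold *or* (with ``include_void``) when they are void: steep flanks
    beyond the detectable slope return no signal, so the void ring around
    the animal belongs to its silhouette, not to the floor.  Side views set
    ``include_void=False``, since there the void background would bridge
    disjoint body parts.  Among connected candidate components the one
    containing the most above-threshold pixels is returned.
    """
    z = frame.heights()
    above = np.isfinite(z) & (z > height_threshold)
    if not above.any():
        raise NothingAboveThresholdError(
            f"no valid pixel above {height_threshold} mm"
        )
    candidates = (above | frame.void_mask) if include_void else above
    labels, n = ndi.label(candidates)
    counts = ndi.sum_labels(above, labels, index=np.arange(1, n + 1))
    best = 1 + int(np.argmax(counts))
    return labels == best


@dataclass
class DerivativeMaps:
    """First/second derivative maps of the elevation field seen by the sensor.

    Gradients are in mm/mm, mean curvature in 1/mm; ``mask`` marks pixels
    with trustworthy derivatives (away from voids and the smoothing stencil).
    ``x``/``y``/``elevation`` give world coordinates and smoothed heights so
    detections can be reported in the leveled frame.
    """

    gradient_x: np.ndarray
    gradient_y: np.ndarray
    gradient_magnitude: np.ndarray
    mean_curvature: np.ndarray
    mask: np.ndarray
    x: np.ndarray
    y: np.ndarray
    elevation: np.ndarray
    pitch: float


def _nan_gaussian(field, valid, sigma_px):
    if sigma_px <= 0:
        return np.where(valid, field, np.nan), valid
    f = np.where(valid, field, 0.0)
    num = ndi.gaussian_filter(f, sigma_px, mode="nearest")
    den = ndi.gaussian_filter(valid.astype(float), sigma_px, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    ok = den > 0.6  # mostly-supported pixels only
    return np.where(ok, sm, np.nan), ok


def derivative_maps(frame: DepthFrame, smoothing_scale: float | None = None,
                    region: np.ndarray | None = None) -> DerivativeMaps:
    """Gradient and mean-curvature maps of a frame's elevation field.

    ``smoothing_scale`` is the Gaussian sigma in mm (default 2 lateral
    pitches) applied before differentiation to suppress background noise
    that would otherwise swamp second derivatives.  Mean curvature uses the
    height-field second-fundamental-form formula; maps are masked within one
    stencil width of void pixels.
    """
    pitch = frame.sensor.lateral_pitch
    if smoothing_scale is None:
        smoothing_scale = 2.0 * pitch
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be non-negative")
    valid = ~frame.void_mask
    if region is not None:
        valid = valid & region
    if valid.sum() < 16:
        raise DegenerateGeometryError("not enough valid pixels for a derivative stencil")

    # elevation toward the sensor, in the camera frame
    e = frame.sensor.working_distance - frame.values
    sigma_px = smoothing_scale / pitch
    e_s, ok = _nan_gaussian(e, valid, sigma_px)

    xg, yg = frame.pixel_grid()
    xc = xg[0, :]
    yc = yg[:, 0]
    with np.errstate(invalid="ignore"):
        ey, ex = np.gradient(e_s, yc, xc)
        exy, exx = np.gradient(ex, yc, xc)
        eyy, _ = np.gradient(ey, yc, xc)
        gmag = np.hypot(ex, ey)
        denom = 2.0 * (1.0 + ex ** 2 + ey ** 2) ** 1.5
        H = (exx * (1 + ey ** 2) - 2 * ex * ey * exy + eyy * (1 + ex ** 2)) / denom

    # trustworthy pixels: supported by data and away from void borders
    guard = max(int(np.ceil(2.0 * sigma_px)), 2)
    mask = ndi.binary_erosion(ok & np.isfinite(H), iterations=guard, border_value=0)

    # world coordinates of each pixel at its smoothed elevation
    r_s = frame.sensor.working_distance - e_s
    R, t = frame.pose[:3, :3], frame.pose[:3, 3]
    world = []
    for i in range(3):
        w = R[i, 0] * xg + R[i, 1] * yg + t[i]
        if R[i, 2] != 0.0:  # keep range-free axes finite where r_s is NaN
            w = w + R[i, 2] * r_s
        world.append(w)
    return DerivativeMaps(
        gradient_x=ex, gradient_y=ey, gradient_magnitude=gmag,
        mean_curvature=H, mask=mask,
        x=world[0], y=world[1], elevation=world[2], pitch=pitch,
    )


class RegistrationError(RuntimeError):
    pass


def _kabsch(src, dst):
    """Best rigid transform (R, t) mapping src onto dst, least squares."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cd - R @ cs


def icp_refine(moving, fixed, cutoff: float = 10.0, max_iterations: int = 50,
               max_points: int = 2000, tol: float = 1e-4):
    """Rigid trimmed point-to-point ICP of ``moving`` onto ``fixed``.

    Correspondences beyond the cutoff (nominally 3x the background noise)
    are discarded each iteration, which keeps partially overlapping views
    from dragging each other; the cutoff anneals from the current match
    distances down to its nominal value.  Returns the 4x4 transform.
    """
    from scipy.spatial import cKDTree

    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    # seeded random subsampling: strided picks alias with the pixel grid and
    # bias the correspondences
    rng = np.random.default_rng(1234)

    def sub_sample(a, m):
        if len(a) <= m:
            return a
        return a[rng.choice(len(a), size=m, replace=False)]

    sub = sub_sample(moving, max_points)
    # keep the reference dense: sparse references bias correspondences
    tree = cKDTree(sub_sample(fixed, max(50 * max_points, 100_000)))
    R_tot = np.eye(3)
    t_tot = np.zeros(3)
    cur = sub
    for _ in range(max_iterations):
        d, idx = tree.query(cur, workers=-1)
        eff = max(cutoff, float(np.percentile(d, 30.0)))
        sel = d <= eff
        if sel.sum() < 10:
            raise RegistrationError(
                "no overlap between views within the correspondence cutoff"
            )
        R, t = _kabsch(cur[sel], tree.data[idx[sel]])
        cur = cur @ R.T + t
        R_tot = R @ R_tot
        t_tot = R @ t_tot + t
        if np.linalg.norm(t) < tol and np.linalg.norm(R - np.eye(3)) < tol:
            break
    # polish: tight-cutoff passes suppress the bias of border correspondences
    for _ in range(3):
        d, idx = tree.query(cur, workers=-1)
        sel = d <= max(2.0 * float(np.median(d)), 0.25 * cutoff)
        if sel.sum() < 10:
            break
        R, t = _kabsch(cur[sel], tree.data[idx[sel]])
        cur = cur @ R.T + t
        R_tot = R @ R_tot
        t_tot = R @ t_tot + t
    M = np.eye(4)
    M[:3, :3] = R_tot
    M[:3, 3] = t_tot
    return M


def register_views(clouds, nominal_poses=None, refine: bool = True,
                   voxel: float | None = None, max_points: int = 2000,
                   max_iterations: int = 50, cutoff: float = 10.0):
    """Merge point clouds after nominal posing and optional ICP refinement.

    ``clouds`` may be world-frame (N, 3) arrays (``nominal_poses=None``) or
    camera-frame arrays with a 4x4 pose each.  Refinement is rigid trimmed
    ICP of each cloud onto the growing merge; the merged cloud is
    deduplicated on a voxel grid.  Rigid-only: within-cloud pairwise
    distances are never changed.
    """
    clouds = [np.asarray(c, float) for c in clouds]
    if not clouds:
        raise ValueError("need at least one cloud")
    if nominal_poses is not None:
        if len(nominal_poses) != len(clouds):
            raise ValueError("one pose per cloud required")
        clouds = [c @ np.asarray(P)[:3, :3].T + np.asarray(P)[:3, 3]
                  for c, P in zip(clouds, nominal_poses)]
    merged = clouds[0]
    for cloud in clouds[1:]:
        moving = cloud
        if refine and len(moving) > 10 and len(merged) > 10:
            M = icp_refine(moving, merged, cutoff=cutoff,
                           max_iterations=max_iterations, max_points=max_points)
            moving = moving @ M[:3, :3].T + M[:3, 3]
        merged = np.vstack([merged, moving])
    if voxel and voxel > 0:
        keys = np.floor(merged / voxel).astype(np.int64)
        _, idx = np.unique(keys, axis=0, return_index=True)
        merged = merged[np.sort(idx)]
    return merged
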