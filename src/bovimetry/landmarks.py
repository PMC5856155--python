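"""Anatomical reference-point detection on filtered depth frames.

Detection rules operate on gradient/curvature maps:

* hips (hook bones), withers and tail head are local surface maxima —
  clusters of null-gradient pixels with negative mean curvature;
* the chest-girth section is the thinnest flank section seen from the side —
  an interior minimum of the per-column vertical body extent (null gradient,
  positive curvature of the extent profile);
* the hoof-floor interface is the height of the strongest second-derivative
  response along the leg silhouette's vertical profile;
* the head border follows from the maximum-detectable-slope cutoff: the
  valid/void boundary of the face lies at the 45-degree slope line, and the
  two head reference points are the midpoints of its left and right arcs.

All landmark positions are reported in the leveled world frame (floor at
z = 0) so downstream parameters are view-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .sensor import DepthFrame
from .surface_ops import DerivativeMaps

__all__ = [
    "Landmark", "detect_local_maxima", "detect_anatomical_maxima",
    "detect_chest_section", "detect_hoof_floor", "detect_head_border",
    "InsufficientLandmarksError", "NoWaistFoundError", "DetectionError",
    "BorderlessHeadError", "GRADIENT_EPS",
]

#: default "null gradient" tolerance (mm/mm): below the slope noise floor of
#: smoothed frames at the sensor's maximum background noise.
GRADIENT_EPS = 0.02


class DetectionError(RuntimeError):
    pass


class InsufficientLandmarksError(DetectionError):
    def __init__(self, expected, found):
        self.expected = expected
        self.found = found
        super().__init__(
            f"expected {expected} landmarks, found {len(found)}: "
            + ", ".join(f"({lm.position[0]:.0f}, {lm.position[1]:.0f})" for lm in found)
        )


class NoWaistFoundError(DetectionError):
    pass


class BorderlessHeadError(DetectionError):
    pass


@dataclass(frozen=True)
class Landmark:
    """Named anatomical point in the leveled world frame (mm)."""

    name: str
    position: np.ndarray
    score: float = 0.0

    @property
    def x(self) -> float:
        return float(self.position[0])

    @property
    def y(self) -> float:
        return float(self.position[1])

    @property
    def z(self) -> float:
        return float(self.position[2])


def detect_local_maxima(maps: DerivativeMaps, region: np.ndarray | None = None,
                        expected: int = 1, grad_eps: float = GRADIENT_EPS,
                        name: str = "maximum") -> list[Landmark]:
    """Local surface maxima: null-gradient, negative-curvature clusters.

    Candidate pixels are clustered by connectivity; each cluster is
    summarised by its curvature-weighted centroid and scored by its mean
    curvature magnitude.  The strongest ``expected`` clusters are returned,
    ties broken by larger cluster area, then by lowest (row, col) index.
    """
    if expected < 1:
        raise ValueError("expected must be >= 1")
    sel = maps.mask
    if region is not None:
        if not region.any():
            raise ValueError("empty search region")
        sel = sel & region
    with np.errstate(invalid="ignore"):
        seeds = sel & (maps.gradient_magnitude < grad_eps) & (maps.mean_curvature < 0)
        grow = sel & (maps.gradient_magnitude < 2.0 * grad_eps) & (maps.mean_curvature < 0)
    # hysteresis: clusters are seeded at the null-gradient tolerance and grown
    # into the surrounding low-gradient basin, which keeps a maximum's cluster
    # connected under gradient noise
    cand = ndi.binary_propagation(seeds, mask=grow)
    labels, n = ndi.label(cand)
    found = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        w = np.abs(maps.mean_curvature[rows, cols])
        wsum = w.sum()
        if wsum <= 0:
            continue
        pos = np.array([
            (maps.x[rows, cols] * w).sum() / wsum,
            (maps.y[rows, cols] * w).sum() / wsum,
            (maps.elevation[rows, cols] * w).sum() / wsum,
        ])
        score = float(wsum / len(rows))
        found.append((score, len(rows), (int(rows.min()), int(cols.min())),
                      Landmark(name=name, position=pos, score=score)))
    found.sort(key=lambda t: (-t[0], -t[1], t[2]))
    landmarks = [t[3] for t in found]
    if len(landmarks) < expected:
        raise InsufficientLandmarksError(expected, landmarks)
    return landmarks[:expected]


def refine_maximum(maps: DerivativeMaps, landmark: Landmark,
                   window_mm: float = 26.0) -> Landmark:
    """Sub-pixel apex from a local quadratic fit of the elevation field.

    Heavily smoothed maps detect prominences robustly but displace their
    apexes down-slope; fitting a quadratic to a lightly smoothed elevation
    patch around the detected position and taking its vertex removes most of
    that bias.  Falls back to the input when the patch is not concave.
    """
    half = window_mm / 2.0
    sel = maps.mask & (np.abs(maps.x - landmark.x) <= half) \
        & (np.abs(maps.y - landmark.y) <= half)
    if sel.sum() < 12:
        return landmark
    dx = maps.x[sel] - landmark.x
    dy = maps.y[sel] - landmark.y
    z = maps.elevation[sel]
    A = np.column_stack([np.ones_like(dx), dx, dy, dx ** 2, dx * dy, dy ** 2])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    H = np.array([[2 * coef[3], coef[4]], [coef[4], 2 * coef[5]]])
    if np.linalg.det(H) <= 0 or H[0, 0] >= 0:
        return landmark
    vx, vy = np.linalg.solve(H, -coef[1:3])
    if max(abs(vx), abs(vy)) > half:
        return landmark
    vz = float(coef @ [1.0, vx, vy, vx ** 2, vx * vy, vy ** 2])
    return Landmark(landmark.name,
                    np.array([landmark.x + vx, landmark.y + vy, vz]),
                    landmark.score)


def detect_anatomical_maxima(maps: DerivativeMaps, body_mask: np.ndarray,
                             grad_eps: float = GRADIENT_EPS,
                             refine_maps: DerivativeMaps | None = None) -> dict:
    """Assign hips, withers and tail head from a top view's maxima.

    Search windows (the anatomy is named but not windowed by the detection
    rule itself): the hip pair is the two strongest maxima within the caudal
    third of the body mask, the withers the strongest within the cranial
    third, the tail head the strongest maximum caudal of the hips.  +x is
    cranial in the leveled frame.
    """
    valid = body_mask & maps.mask
    if not valid.any():
        raise DetectionError("body mask carries no valid derivative pixels")
    xs = maps.x[valid]
    x_min, x_max = float(xs.min()), float(xs.max())
    third = (x_max - x_min) / 3.0
    caudal = body_mask & (maps.x <= x_min + third)
    cranial = body_mask & (maps.x >= x_max - third)

    candidates = detect_local_maxima(maps, caudal, expected=2,
                                     grad_eps=grad_eps, name="hip")
    hips = _distinct_pair(candidates, min_sep=5.0 * maps.pitch, maps=maps,
                          region=caudal, grad_eps=grad_eps)
    hip_left = max(hips, key=lambda lm: lm.y)
    hip_right = min(hips, key=lambda lm: lm.y)

    withers = detect_local_maxima(maps, cranial, expected=1,
                                  grad_eps=grad_eps, name="withers")[0]

    tail_region = body_mask & (maps.x < min(h.x for h in hips) - 2.0 * maps.pitch)
    tail = detect_local_maxima(maps, tail_region, expected=1,
                               grad_eps=grad_eps, name="tail_head")[0]
    out = {
        "hip_left": Landmark("hip_left", hip_left.position, hip_left.score),
        "hip_right": Landmark("hip_right", hip_right.position, hip_right.score),
        "withers": withers,
        "tail_head": tail,
    }
    if refine_maps is not None:
        out = {k: refine_maximum(refine_maps, lm) for k, lm in out.items()}
    return out


def _distinct_pair(candidates, min_sep, maps, region, grad_eps):
    """Top-two maxima at least ``min_sep`` apart; widen the pool if needed."""
    first = candidates[0]
    if np.linalg.norm(candidates[1].position - first.position) >= min_sep:
        return [first, candidates[1]]
    pool = detect_local_maxima(maps, region, expected=2, grad_eps=grad_eps,
                               name="hip")
    try:
        pool = detect_local_maxima(maps, region, expected=len(pool) + 8,
                                   grad_eps=grad_eps, name="hip")
    except InsufficientLandmarksError as exc:
        pool = exc.found
    for other in pool[1:]:
        if np.linalg.norm(other.position - first.position) >= min_sep:
            return [first, other]
    raise InsufficientLandmarksError(2, [first])


def flank_extent_profile(side_frame: DepthFrame, body_mask: np.ndarray,
                         smooth_px: float = 4.0):
    """Per-column vertical extent (mm) of the body seen from the side.

    Returns (x_world, extent) for columns holding body pixels; extent is the
    z span of the masked pixels, lightly smoothed along the body axis.
    """
    z = side_frame.heights()
    ok = body_mask & np.isfinite(z)
    zmax = np.where(ok, z, -np.inf).max(axis=0)
    zmin = np.where(ok, z, np.inf).min(axis=0)
    has = ok.any(axis=0)
    extent = np.where(has, zmax - zmin, np.nan)
    xg, _ = side_frame.pixel_grid()
    R, t = side_frame.pose[:3, :3], side_frame.pose[:3, 3]
    x_world = xg[0, :] * R[0, 0] + t[0]
    if smooth_px > 0 and has.sum() > 8:
        filled = extent.copy()
        idx = np.nonzero(has)[0]
        sm = ndi.gaussian_filter1d(extent[idx], smooth_px, mode="nearest")
        filled[idx] = sm
        extent = filled
    return x_world, extent


def topline_profile(side_frame: DepthFrame, body_mask: np.ndarray,
                    smooth_px: float = 3.0):
    """Per-column height of the flank's upper visible edge (mm).

    For a vertically symmetric cross-section the flank extent is
    proportional to the topline height above the section centre, so the
    upper edge carries the same waist signal as the full extent while being
    immune to leg occlusion of the belly line.
    """
    z = side_frame.heights()
    ok = body_mask & np.isfinite(z)
    top = np.where(ok, z, -np.inf).max(axis=0)
    has = ok.any(axis=0)
    prof = np.where(has, top, np.nan)
    xg, _ = side_frame.pixel_grid()
    R, t = side_frame.pose[:3, :3], side_frame.pose[:3, 3]
    x_world = xg[0, :] * R[0, 0] + t[0]
    if smooth_px > 0 and has.sum() > 8:
        idx = np.nonzero(has)[0]
        prof[idx] = ndi.gaussian_filter1d(prof[idx], smooth_px, mode="nearest")
    return x_world, prof


def _parabolic_refine(x, y, i, half_window: int = 30):
    """Vertex of a least-squares parabola around index ``i``; falls back to
    the discrete position when the fit is not convex."""
    lo = i - half_window
    hi = i + half_window + 1
    lo = max(lo, 0)
    hi = min(hi, len(y))
    sel = slice(lo, hi)
    xs, ys = x[sel], y[sel]
    good = np.isfinite(ys)
    if good.sum() < 7:
        return float(x[i])
    coef = np.polyfit(xs[good] - x[i], ys[good], 2)
    if coef[0] <= 0:
        return float(x[i])
    vertex = float(x[i] - coef[1] / (2 * coef[0]))
    if not (x[sel][0] <= vertex <= x[sel][-1]) and not (
            x[sel][-1] <= vertex <= x[sel][0]):
        return float(x[i])
    return vertex


def detect_chest_section(side_frame: DepthFrame, body_mask: np.ndarray,
                         cranial_half_only: bool = True) -> Landmark:
    """Thinnest flank section: interior minimum of the flank profile.

    The chest-girth position shows a null gradient with positive curvature
    of the per-column flank profile (topline height, see
    :func:`topline_profile`).  The deepest interior local minimum is
    returned, ties going to the more cranial (larger x) position; the
    minimum is refined to sub-pixel precision with a parabolic fit.
    """
    x_world, extent = topline_profile(side_frame, body_mask)
    has = np.isfinite(extent)
    idx = np.nonzero(has)[0]
    if len(idx) < 5:
        raise DetectionError("body mask spans too few columns")
    # restrict to a contiguous column window; optionally the cranial half
    lo, hi = idx.min(), idx.max()
    x_lo, x_hi = x_world[lo], x_world[hi]
    if x_lo > x_hi:
        x_lo, x_hi = x_hi, x_lo
    x_mid = 0.5 * (x_lo + x_hi)
    minima = []
    for i in idx[1:-1]:
        if not (has[i - 1] and has[i + 1]):
            continue
        if cranial_half_only and x_world[i] < x_mid:
            continue
        if extent[i] < extent[i - 1] and extent[i] <= extent[i + 1]:
            minima.append(i)
    if not minima:
        raise NoWaistFoundError("no interior minimum of the flank profile")
    depth_key = lambda i: (extent[i], -x_world[i])
    best = min(minima, key=depth_key)
    x_star = _parabolic_refine(x_world, extent, best)
    z = side_frame.heights()
    col_ok = body_mask[:, best] & np.isfinite(z[:, best])
    z_mid = 0.5 * (z[col_ok, best].max() + z[col_ok, best].min())
    return Landmark("chest_section", np.array([x_star, 0.0, z_mid]),
                    score=float(-extent[best]))


def detect_hoof_floor(side_frame: DepthFrame, leg_region: np.ndarray) -> Landmark:
    """Hoof-floor interface from the leg silhouette's vertical profile.

    The silhouette width per row is differentiated twice; the row of maximum
    second-derivative magnitude (the sharpest slope variation, i.e. the
    hoof-to-floor corner) gives the interface height.
    """
    z = side_frame.heights()
    ok = leg_region & np.isfinite(z)
    if not ok.any():
        raise DetectionError("leg region holds no valid pixels")
    width = ok.sum(axis=1).astype(float) * side_frame.sensor.lateral_pitch
    rows = np.arange(len(width))
    # row height coordinate: mean z of pixels in the row (rows are iso-z for
    # canonical side views); fall back to pixel-grid y for empty rows
    _, yg = side_frame.pixel_grid()
    R, t = side_frame.pose[:3, :3], side_frame.pose[:3, 3]
    row_z = yg[:, 0] * R[2, 1] + t[2]
    d2 = np.abs(np.diff(width, n=2))
    if d2.max() <= 1e-9:
        raise DetectionError("no slope variation along the leg profile")
    # among comparably strong slope variations take the lowest one: the leg
    # silhouette also has a corner where it meets the trunk, but the
    # hoof-floor interface is at the bottom
    strong = np.nonzero(d2 >= 0.8 * d2.max())[0] + 1
    i = int(min(strong, key=lambda j: row_z[j]))
    span = ok.any(axis=1)
    if not span[max(i - 3, 0):i + 4].any():
        raise DetectionError("profile transition lies outside the leg region")
    cols = np.nonzero(ok[min(i + 1, len(rows) - 1)] | ok[i])[0]
    xg, _ = side_frame.pixel_grid()
    x_world = float(np.mean(xg[0, cols] * R[0, 0] + t[0])) if len(cols) else 0.0
    return Landmark("hoof_floor", np.array([x_world, 0.0, float(row_z[i])]),
                    score=float(d2.max()))


def detect_head_border(front_frame: DepthFrame, min_component_px: int = 200,
                       ) -> tuple[Landmark, Landmark]:
    """Head reference points from the 45-degree slope border.

    The face's valid region is bounded by void pixels where the surface
    reaches the maximum detectable slope.  The nearest-to-camera valid
    component is taken as the head; its valid/void boundary is split into
    left and right arcs about the face axis and each arc's midpoint (median
    point along the arc) is returned.
    """
    valid = ~front_frame.void_mask
    labels, n = ndi.label(valid)
    if n == 0:
        raise BorderlessHeadError("frame holds no valid pixels")
    comps = []
    for lab in range(1, n + 1):
        m = labels == lab
        if m.sum() < min_component_px:
            continue
        comps.append((float(np.nanmean(front_frame.values[m])), lab, m))
    if not comps:
        raise BorderlessHeadError("no sizeable valid component in the front view")
    comps.sort(key=lambda t: (t[0], t[1]))
    _, _, head = comps[0]

    dilated = ndi.binary_dilation(head)
    boundary = head & ndi.binary_dilation(front_frame.void_mask) & ~ndi.binary_erosion(head)
    if not boundary.any() or not (dilated & front_frame.void_mask).any():
        raise BorderlessHeadError(
            "head component has no void border; lower the maximum slope or "
            "move the sensor closer"
        )
    rows, cols = np.nonzero(boundary)
    xg, yg = front_frame.pixel_grid()
    R, t = front_frame.pose[:3, :3], front_frame.pose[:3, 3]
    pts_cam = np.column_stack([xg[rows, cols], yg[rows, cols],
                               front_frame.values[rows, cols]])
    pts = pts_cam @ R.T + t
    axis_y = pts[:, 1].mean()
    out = []
    for side, sel in (("left", pts[:, 1] >= axis_y), ("right", pts[:, 1] < axis_y)):
        if sel.sum() < 3:
            raise BorderlessHeadError(f"head border {side} arc too short")
        arc = pts[sel]
        order = np.argsort(arc[:, 2])  # arcs run vertically; z orders arc length
        mid = arc[order[len(order) // 2]]
        out.append(Landmark(f"head_border_{side}", mid,
                            score=float(sel.sum())))
    return out[0], out[1]
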