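"""The seven body parameters, computed from landmarks and merged clouds.

Parameters (mm unless noted): hip distance, body length (withers to tail
head), front/back/average height, back slope (degrees), chest girth, body
depth and head size.  Definitions:

* lateral distances (hip distance, body length) are Euclidean distances
  after projection to the floor plane;
* heights are landmark heights above the datum (the leveled floor, or the
  hoof-floor landmark when the floor is shadowed);
* back slope = arctan((front_height - back_height) / hips-to-withers
  length); positive when the withers stand higher than the hips;
* chest girth is the perimeter (Ramanujan's second approximation) of a
  least-squares ellipse fitted to the chest cross-section slab of the
  merged cloud;
* depth = average height minus the vertical extent of the chest section;
* head size is the distance between the two 45-degree head border points.

Each parameter is finally the average over repeated captures
(:func:`aggregate_repeats`), ten by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .landmarks import Landmark

__all__ = [
    "BodyParameters", "GirthResult", "hip_distance", "body_length", "heights",
    "back_slope", "chest_girth", "body_depth", "head_size",
    "aggregate_repeats", "ramanujan_perimeter", "PARAMETER_FIELDS",
    "ImplausibleValueWarning", "LowCoverageWarning", "InconsistentGeometryError",
]

PARAMETER_FIELDS = (
    "hip_distance", "body_length", "front_height", "back_height",
    "average_height", "back_slope", "chest_girth", "depth", "head_size",
)


class ImplausibleValueWarning(UserWarning):
    pass


class LowCoverageWarning(UserWarning):
    pass


class InconsistentGeometryError(ValueError):
    pass


@dataclass
class BodyParameters:
    """One animal's body parameters (mm; back_slope in degrees).

    ``dispersion`` holds the per-parameter sample standard deviation across
    repeats when the instance is an aggregate.
    """

    hip_distance: float = math.nan
    body_length: float = math.nan
    front_height: float = math.nan
    back_height: float = math.nan
    average_height: float = math.nan
    back_slope: float = math.nan
    chest_girth: float = math.nan
    depth: float = math.nan
    head_size: float = math.nan
    n_repeats: int = 1
    dispersion: Optional[dict] = field(default=None)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAMETER_FIELDS}


def _floor_projected(landmark: Landmark) -> np.ndarray:
    return np.array([landmark.x, landmark.y])


def hip_distance(hip_left: Landmark, hip_right: Landmark) -> float:
    """Distance between the hook-bone apexes, projected to the floor plane."""
    d = float(np.linalg.norm(_floor_projected(hip_left) - _floor_projected(hip_right)))
    if d < 50.0:
        warnings.warn(
            f"hip distance {d:.1f} mm is implausibly small", ImplausibleValueWarning
        )
    return d


def body_length(withers: Landmark, tail_head: Landmark) -> float:
    """Withers to tail head distance, projected to the floor plane."""
    return float(np.linalg.norm(_floor_projected(withers) - _floor_projected(tail_head)))


def heights(withers: Landmark, hip_left: Landmark, hip_right: Landmark,
            datum: float = 0.0) -> tuple[float, float, float]:
    """(front, back, average) heights above the datum.

    Front height is taken at the withers, back height at the midpoint of the
    hip pair.  ``datum`` is 0 for a leveled floor, or the hoof-floor
    landmark height when the floor is not reconstructed.
    """
    front = withers.z - datum
    back = 0.5 * (hip_left.z + hip_right.z) - datum
    return front, back, 0.5 * (front + back)


def back_slope(front_height: float, back_height: float,
               hips_to_withers_length: float) -> float:
    """Topline angle in degrees; positive when the withers stand higher."""
    if hips_to_withers_length <= 0:
        raise ValueError("hips-to-withers length must be positive")
    return math.degrees(math.atan((front_height - back_height) / hips_to_withers_length))


def ramanujan_perimeter(semi_a: float, semi_b: float) -> float:
    """Ellipse perimeter by Ramanujan's second approximation.

    Relative error is below 1e-6 for the aspect ratios of bovine chest
    sections (b/a > 0.5).
    """
    if semi_a <= 0 or semi_b <= 0:
        raise ValueError("semi-axes must be positive")
    h = ((semi_a - semi_b) / (semi_a + semi_b)) ** 2
    return math.pi * (semi_a + semi_b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


@dataclass(frozen=True)
class GirthResult:
    """Chest-girth measurement: perimeter plus the fitted section ellipse."""

    perimeter: float
    center: tuple[float, float]       # (y, z) of the section ellipse, mm
    semi_axes: tuple[float, float]    # fitted semi-axes, mm
    theta: float                      # ellipse rotation, radians
    vertical_extent: float            # full vertical extent of the ellipse, mm
    coverage: float                   # fraction of the perimeter seen by data
    n_points: int

    def __float__(self):
        return self.perimeter


def chest_girth(merged_cloud, chest_x: float, slab_width: float = 30.0,
                min_coverage: float = 0.4) -> GirthResult:
    """Girth of the chest cross-section from a merged multi-view cloud.

    A slab of half-width ``slab_width/2`` about ``chest_x`` is projected to
    the (y, z) plane and a least-squares ellipse is fitted; the perimeter is
    Ramanujan's second approximation.  Coverage below ``min_coverage``
    attaches a warning (the belly is typically unseen), a degenerate fit
    raises.
    """
    from skimage.measure import EllipseModel

    pts = np.asarray(merged_cloud, float)
    sel = np.abs(pts[:, 0] - chest_x) <= slab_width / 2.0
    section = pts[sel][:, 1:3]
    if len(section) < 20:
        raise InconsistentGeometryError(
            f"chest slab at x = {chest_x:.0f} mm holds only {len(section)} points"
        )
    def fit(points):
        if hasattr(EllipseModel, "from_estimate"):
            model = EllipseModel.from_estimate(points)
            if not model:
                raise InconsistentGeometryError(
                    "degenerate chest section: ellipse fit failed"
                )
            (yc_, zc_), (a_, b_) = model.center, model.axis_lengths
            return yc_, zc_, a_, b_, model.theta
        model = EllipseModel()
        if not model.estimate(points) or model.params is None:
            raise InconsistentGeometryError(
                "degenerate chest section: ellipse fit failed"
            )
        return model.params

    yc, zc, a, b, theta = fit(section)
    # trimming passes: points far off the fitted ellipse (stray leg/floor
    # returns or bump tails in the slab) are discarded and the ellipse
    # refitted; the threshold is ~2.5x the sensor noise in mm
    for threshold_mm in (15.0, 8.0):
        ct0, st0 = math.cos(-theta), math.sin(-theta)
        rel0 = section - [yc, zc]
        u0 = (rel0[:, 0] * ct0 - rel0[:, 1] * st0) / a
        v0 = (rel0[:, 0] * st0 + rel0[:, 1] * ct0) / b
        rho = np.hypot(u0, v0)
        dist_mm = np.abs(rho - 1.0) * min(a, b)
        keep = dist_mm < threshold_mm
        if keep.sum() >= 20 and keep.sum() < len(section):
            section = section[keep]
            yc, zc, a, b, theta = fit(section)
    if a <= 0 or b <= 0 or max(a, b) / min(a, b) > 10:
        raise InconsistentGeometryError("degenerate chest section ellipse")
    # angular coverage of the fitted ellipse by the data
    rel = section - [yc, zc]
    ct, st = math.cos(-theta), math.sin(-theta)
    u = rel[:, 0] * ct - rel[:, 1] * st
    v = rel[:, 0] * st + rel[:, 1] * ct
    ang = np.arctan2(v / b, u / a)
    nbins = 64
    cov = len(np.unique(((ang + np.pi) / (2 * np.pi) * nbins).astype(int) % nbins)) / nbins
    if cov < min_coverage:
        warnings.warn(
            f"chest section coverage {cov:.0%} below {min_coverage:.0%}",
            LowCoverageWarning,
        )
    vert = 2.0 * math.hypot(a * math.sin(theta), b * math.cos(theta))
    return GirthResult(
        perimeter=ramanujan_perimeter(a, b), center=(float(yc), float(zc)),
        semi_axes=(float(a), float(b)), theta=float(theta),
        vertical_extent=float(vert), coverage=float(cov), n_points=int(len(section)),
    )


def body_depth(average_height: float, chest_vertical_extent: float) -> float:
    """Chest-to-floor clearance: average height minus chest vertical extent."""
    if chest_vertical_extent < 0:
        raise ValueError("chest vertical extent must be non-negative")
    if chest_vertical_extent > average_height:
        raise InconsistentGeometryError(
            f"chest extent {chest_vertical_extent:.0f} mm exceeds the average "
            f"height {average_height:.0f} mm"
        )
    return average_height - chest_vertical_extent


def head_size(border_left: Landmark, border_right: Landmark) -> float:
    """Distance between the left and right 45-degree head border midpoints."""
    return float(np.linalg.norm(border_left.position - border_right.position))


def aggregate_repeats(results: list[BodyParameters]) -> BodyParameters:
    """Per-parameter mean and sample standard deviation over repeats."""
    if not results:
        raise ValueError("need at least one repeat to aggregate")
    agg = BodyParameters(n_repeats=len(results))
    dispersion = {}
    for name in PARAMETER_FIELDS:
        vals = np.array([getattr(r, name) for r in results], float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        setattr(agg, name, float(vals.mean()))
        dispersion[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    agg.dispersion = dispersion
    return agg
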