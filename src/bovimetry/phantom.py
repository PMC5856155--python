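"""Parametric cow phantom with closed-form ground truth for every body parameter.

The phantom is an analytic solid: a superellipsoid-like torso (elliptical
cross-section at the chest blending into a flat-topped superelliptical
cross-section over the rump), Gaussian-profile bumps for the anatomical
prominences (hook bones, withers, tail head), a multiplicative axial waist
behind the front legs, four vertical leg cylinders and an ellipsoidal head.

Every body parameter has a ground-truth value derived from the generating
parameters alone: bump apexes and the waist minimum are located by
extremizing the analytic surface functions (never by measuring a rendered
frame), and the chest girth is the arc length of the analytic cross-section.

Coordinate convention: world frame with the floor at z = 0, +z up, +x toward
the head (cranial), y lateral.  All lengths in millimetres, angles in
degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.integrate import quad

__all__ = [
    "CowPhantom",
    "GroundTruthParameters",
    "generate_cow_phantom",
    "PHANTOM_PRESETS",
]


@dataclass(frozen=True)
class GroundTruthParameters:
    """Closed-form reference values for the seven body parameters (mm / deg)."""

    hip_distance: float
    body_length: float
    front_height: float
    back_height: float
    average_height: float
    back_slope: float
    chest_girth: float
    depth: float
    head_size: float
    # auxiliary geometry, useful for targeted tests and search windows
    x_withers: float = 0.0
    x_tail: float = 0.0
    x_hips: float = 0.0
    y_hip: float = 0.0
    x_chest: float = 0.0
    chest_semi_y: float = 0.0
    chest_semi_z: float = 0.0
    hips_to_withers: float = 0.0
    head_length: float = 0.0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CowPhantom:
    """Analytic cow body; all parameters in mm unless noted.

    Torso: implicit surface with axial profile ``s(x) = (1 - |x/a|^px)^(1/2)``,
    waist factor ``w(x)`` and a cross-section exponent ``q(x)`` that is 2
    (ellipse) cranially and ``rump_q`` (flat-topped superellipse) caudally.
    """

    # torso
    a: float = 350.0          # half length
    b: float = 150.0          # half width at the widest section
    c: float = 195.0          # half height of the cross-section
    zc: float = 420.0         # torso centre height above floor
    px: float = 6.0           # axial superellipse exponent
    rump_q: float = 6.0       # caudal cross-section exponent
    blend_x: float = -63.0    # centre of the q(x) blend (typically -0.18 a)
    blend_w: float = 17.5     # blend width (typically 0.05 a)
    # chest waist (multiplicative narrowing, minimum near waist_x)
    waist_depth: float = 0.10
    waist_x: float = 38.0
    waist_sigma: float = 70.0
    # hook-bone (hip) bumps at (hip_x, +-hip_y)
    hip_x: float = -140.0
    hip_y: float = 74.0
    hip_amp: float = 21.0
    hip_sigma: float = 33.0
    # withers bump at (withers_x, 0)
    withers_x: float = 155.0
    withers_amp: float = 26.0
    withers_sigma: float = 40.0
    # tail-head bump at (tail_x, 0)
    tail_x: float = -210.0
    tail_amp: float = 15.0
    tail_sigma: float = 29.0
    # legs (vertical cylinders from the floor into the torso)
    leg_radius: float = 27.0
    front_leg_x: float = 147.0
    rear_leg_x: float = -147.0
    leg_y: float = 82.0
    # head (ellipsoid, separate blob ahead of the torso)
    head_hx: float = 55.0
    head_hy: float = 68.0
    head_hz: float = 80.0
    head_gap: float = 40.0
    head_z: float = 400.0

    truth: Optional[GroundTruthParameters] = field(default=None, compare=False)

    def __post_init__(self):
        self._validate()
        if self.truth is None:
            object.__setattr__(self, "truth", self._compute_truth())

    # ---------------------------------------------------------------- geometry

    def _validate(self):
        positive = (
            "a b c zc hip_amp hip_sigma withers_amp withers_sigma tail_amp "
            "tail_sigma leg_radius head_hx head_hy head_hz waist_sigma"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"phantom parameter {name} must be positive")
        if not (0 <= self.waist_depth < 1):
            raise ValueError("waist_depth must lie in [0, 1) (waist narrower than torso)")
        if self.zc - self.c <= 0:
            raise ValueError("torso underside below the floor (zc <= c)")
        if not (-self.a < self.tail_x < self.hip_x < 0 < self.withers_x < self.a):
            raise ValueError("bump ordering must be tail < hips < 0 < withers within the torso")
        if abs(self.hip_y) >= self.b:
            raise ValueError("hip bumps must lie on the torso upper surface (|hip_y| < b)")

    def head_center(self) -> np.ndarray:
        return np.array([self.a + self.head_gap + self.head_hx, 0.0, self.head_z])

    def axial_profile(self, x):
        """s(x): relative cross-section size, 0 at the torso ends, ~1 centrally."""
        u = np.minimum(np.abs(np.asarray(x, float)) / self.a, 1.0)
        return np.sqrt(np.maximum(1.0 - u ** self.px, 0.0))

    def waist_factor(self, x):
        x = np.asarray(x, float)
        return 1.0 - self.waist_depth * np.exp(
            -((x - self.waist_x) ** 2) / (2.0 * self.waist_sigma ** 2)
        )

    def section_scale(self, x):
        """S(x) = s(x) * w(x); cross-section semi-axes are b*S and c*S."""
        return self.axial_profile(x) * self.waist_factor(x)

    def section_exponent(self, x):
        """q(x): 2 cranially, rump_q caudally, tanh blend."""
        x = np.asarray(x, float)
        t = 0.5 * (1.0 - np.tanh((x - self.blend_x) / self.blend_w))
        return 2.0 + (self.rump_q - 2.0) * t

    def bump_height(self, x, y):
        """Summed Gaussian prominences (hooks, withers, tail head) at (x, y)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.zeros(np.broadcast(x, y).shape)
        for (x0, y0, amp, sig) in (
            (self.hip_x, +self.hip_y, self.hip_amp, self.hip_sigma),
            (self.hip_x, -self.hip_y, self.hip_amp, self.hip_sigma),
            (self.withers_x, 0.0, self.withers_amp, self.withers_sigma),
            (self.tail_x, 0.0, self.tail_amp, self.tail_sigma),
        ):
            out = out + amp * np.exp(
                -(((x - x0) ** 2) + (y - y0) ** 2) / (2.0 * sig ** 2)
            )
        return out

    def torso_top(self, x, y, bumps: bool = True):
        """Upper torso surface height z(x, y); NaN outside the footprint."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        S = self.section_scale(x)
        q = self.section_exponent(x)
        B = self.b * S
        C = self.c * S
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.abs(y) / np.where(B > 0, B, np.nan)
            core = 1.0 - u ** q
            z = self.zc + C * np.where(core > 0, core, np.nan) ** (1.0 / q)
        if bumps:
            z = z + self.bump_height(x, y)
        return np.where((np.abs(x) < self.a) & (core > 0), z, np.nan)

    def torso_halfwidth(self, x, z):
        """Flank surface |y|(x, z); NaN outside the torso (bumps excluded:
        their normals exceed the 45 deg cutoff from any side view)."""
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        S = self.section_scale(x)
        q = self.section_exponent(x)
        B = self.b * S
        C = self.c * S
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.abs(z - self.zc) / np.where(C > 0, C, np.nan)
            core = 1.0 - v ** q
            y = B * np.where(core > 0, core, np.nan) ** (1.0 / q)
        return np.where((np.abs(x) < self.a) & (core > 0), y, np.nan)

    def torso_nose(self, y, z):
        """Cranial end-cap surface x(y, z); NaN off the cap.

        Uses the elliptical (q = 2) section that holds cranially; the waist
        factor is ~1 at the cap and is ignored.
        """
        y = np.asarray(y, float)
        z = np.asarray(z, float)
        rho2 = (y / self.b) ** 2 + ((z - self.zc) / self.c) ** 2
        with np.errstate(invalid="ignore"):
            x = self.a * np.where(rho2 < 1, 1.0 - rho2, np.nan) ** (1.0 / self.px)
        return x

    def head_top(self, x, y):
        cx, _, cz = self.head_center()
        r2 = ((np.asarray(x, float) - cx) / self.head_hx) ** 2 + (
            np.asarray(y, float) / self.head_hy
        ) ** 2
        with np.errstate(invalid="ignore"):
            return np.where(r2 < 1, cz + self.head_hz * np.sqrt(np.maximum(1 - r2, 0)), np.nan)

    def head_halfwidth(self, x, z):
        cx, _, cz = self.head_center()
        r2 = ((np.asarray(x, float) - cx) / self.head_hx) ** 2 + (
            (np.asarray(z, float) - cz) / self.head_hz
        ) ** 2
        with np.errstate(invalid="ignore"):
            return np.where(r2 < 1, self.head_hy * np.sqrt(np.maximum(1 - r2, 0)), np.nan)

    def head_front(self, y, z):
        cx, _, cz = self.head_center()
        r2 = (np.asarray(y, float) / self.head_hy) ** 2 + (
            (np.asarray(z, float) - cz) / self.head_hz
        ) ** 2
        with np.errstate(invalid="ignore"):
            return np.where(r2 < 1, cx + self.head_hx * np.sqrt(np.maximum(1 - r2, 0)), np.nan)

    def leg_positions(self):
        return [
            (self.front_leg_x, +self.leg_y), (self.front_leg_x, -self.leg_y),
            (self.rear_leg_x, +self.leg_y), (self.rear_leg_x, -self.leg_y),
        ]

    # ------------------------------------------------------------------ truth

    def _apex(self, x0, y0, two_d):
        """Locate a local maximum of the bumped torso top near (x0, y0)."""

        def neg_top(x, y):
            z = float(self.torso_top(x, y))
            return -z if np.isfinite(z) else 1e12

        if two_d:
            res = optimize.minimize(
                lambda p: neg_top(p[0], p[1]),
                x0=np.array([x0, y0 * 0.85]),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000},
            )
            xs, ys = res.x
        else:
            half = 2.5 * max(self.withers_sigma, self.tail_sigma)
            res = optimize.minimize_scalar(
                lambda x: neg_top(x, y0),
                bounds=(max(x0 - half, -self.a + 1e-6),
                        min(x0 + half, self.a - 1e-6)),
                method="bounded",
                options={"xatol": 1e-9},
            )
            xs, ys = res.x, y0
        z = float(self.torso_top(xs, ys))
        if not np.isfinite(z):
            raise ValueError("bump apex search left the torso surface; spec is degenerate")
        return float(xs), float(ys), z

    def _chest_x(self):
        """Axial position of the thinnest flank section (minimum of S(x))
        restricted to the cranial half of the torso."""
        res = optimize.minimize_scalar(
            lambda x: float(self.section_scale(x)),
            bounds=(0.05 * self.a, 0.50 * self.a),
            method="bounded",
            options={"xatol": 1e-9},
        )
        xc = float(res.x)
        lo, hi = 0.05 * self.a, 0.50 * self.a
        if min(xc - lo, hi - xc) < 1e-3 * self.a:
            raise ValueError("no interior chest waist in the cranial half")
        return xc

    def section_perimeter(self, x: float) -> float:
        """Arc length of the cross-section superellipse at x (quadrature)."""
        S = float(self.section_scale(x))
        q = float(self.section_exponent(x))
        B, C = self.b * S, self.c * S
        e = 2.0 / q

        def speed(t):
            ct, st = math.cos(t), math.sin(t)
            dx = -B * e * (ct ** (e - 1.0)) * st if ct > 0 else 0.0
            dy = C * e * (st ** (e - 1.0)) * ct if st > 0 else 0.0
            return math.hypot(dx, dy)

        length, _ = quad(speed, 0.0, math.pi / 2.0, limit=200)
        return 4.0 * length

    def _compute_truth(self) -> GroundTruthParameters:
        xw, _, zw = self._apex(self.withers_x, 0.0, two_d=False)
        xt, _, _zt = self._apex(self.tail_x, 0.0, two_d=False)
        xh, yh, zh = self._apex(self.hip_x, self.hip_y, two_d=True)
        if abs(yh) < 0.5 * self.hip_y:
            raise ValueError(
                "hip bump does not form a distinct lateral maximum "
                "(bump too weak for the flank slope)"
            )
        if not (xt < xh < xw):
            raise ValueError("bump apexes out of anatomical order")

        front_height = zw
        back_height = zh  # both hip apexes share z by symmetry
        average_height = 0.5 * (front_height + back_height)
        hips_to_withers = xw - xh
        back_slope = math.degrees(
            math.atan((front_height - back_height) / hips_to_withers)
        )

        xc = self._chest_x()
        S = float(self.section_scale(xc))
        semi_y, semi_z = self.b * S, self.c * S
        girth = self.section_perimeter(xc)
        depth = average_height - 2.0 * semi_z

        hx, hy = self.head_hx, self.head_hy
        y_star = hy ** 2 / math.hypot(hx, hy)
        head_size = 2.0 * y_star
        cx = float(self.head_center()[0])
        x_border = cx + hx ** 2 / math.hypot(hx, hy)
        head_length = math.hypot((cx + hx) - x_border, y_star)

        return GroundTruthParameters(
            hip_distance=2.0 * abs(yh),
            body_length=xw - xt,
            front_height=front_height,
            back_height=back_height,
            average_height=average_height,
            back_slope=back_slope,
            chest_girth=girth,
            depth=depth,
            head_size=head_size,
            x_withers=xw, x_tail=xt, x_hips=xh, y_hip=abs(yh), x_chest=xc,
            chest_semi_y=semi_y, chest_semi_z=semi_z,
            hips_to_withers=hips_to_withers, head_length=head_length,
        )

    # ------------------------------------------------------------------ misc

    def scaled(self, factor: float) -> "CowPhantom":
        """Uniformly scaled copy (all lengths multiplied; waist_depth and
        exponents unchanged)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        lengths = {
            f.name: getattr(self, f.name) * factor
            for f in fields(self)
            if f.name not in ("px", "rump_q", "waist_depth", "truth")
        }
        return replace(self, truth=None, **lengths)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Loose axis-aligned bounding box of the whole phantom (mm)."""
        hc = self.head_center()
        lo = np.array([-self.a - 3 * self.tail_sigma, -self.b - 1.0, 0.0])
        hi = np.array([
            hc[0] + self.head_hx,
            self.b + 1.0,
            max(self.zc + self.c + self.hip_amp + self.withers_amp, hc[2] + self.head_hz),
        ])
        return lo, hi


# -------------------------------------------------------------------- presets

# Each entry: parameter -> (low, high) of a uniform draw, expressed in units of
# the drawn torso half-length `a` where the comment says so.
PHANTOM_PRESETS = {
    # young-calf scale: fits the 730 x 550 mm field of view of a 1 m capture
    "calf": dict(
        a=(300.0, 400.0),
        b_over_a=(0.40, 0.47),
        c_over_b=(1.15, 1.35),
        belly_clearance=(150.0, 210.0),
        waist_x_rel=(0.06, 0.16),
        waist_depth=(0.08, 0.14),
        waist_sigma=(55.0, 75.0),
        hip_x_rel=(-0.44, -0.36),
        hip_u=(0.50, 0.60),       # hip_y as a fraction of the local half-width
        hip_amp=(18.0, 24.0),
        hip_sigma=(30.0, 36.0),
        withers_x_rel=(0.38, 0.46),
        withers_amp=(22.0, 30.0),
        withers_sigma=(36.0, 44.0),
        tail_dx_rel=(0.16, 0.20),  # caudal offset of the tail bump from the hips
        tail_amp=(14.0, 17.0),
        tail_sigma=(27.0, 32.0),
        leg_radius=(22.0, 30.0),
        head_hx=(45.0, 65.0),
        head_hy=(55.0, 80.0),
        head_hz=(65.0, 95.0),
        head_z_rel=(0.80, 1.00),   # fraction of zc
    ),
    # young-cow scale: intended for the 2 m working distance (1250 x 950 mm FOV)
    "cow": dict(
        a=(450.0, 600.0),
        b_over_a=(0.40, 0.47),
        c_over_b=(1.15, 1.35),
        belly_clearance=(260.0, 360.0),
        waist_x_rel=(0.06, 0.16),
        waist_depth=(0.08, 0.14),
        waist_sigma=(80.0, 105.0),
        hip_x_rel=(-0.44, -0.36),
        hip_u=(0.50, 0.60),
        hip_amp=(26.0, 34.0),
        hip_sigma=(44.0, 52.0),
        withers_x_rel=(0.38, 0.46),
        withers_amp=(32.0, 44.0),
        withers_sigma=(52.0, 64.0),
        tail_dx_rel=(0.16, 0.21),
        tail_amp=(60.0, 74.0),
        tail_sigma=(62.0, 76.0),
        leg_radius=(32.0, 42.0),
        head_hx=(60.0, 85.0),
        head_hy=(75.0, 105.0),
        head_hz=(90.0, 125.0),
        head_z_rel=(0.80, 1.00),
    ),
}


def generate_cow_phantom(spec="calf", seed: int = 0) -> CowPhantom:
    """Random phantom drawn uniformly from a preset's parameter ranges.

    ``spec`` is a preset name ("calf", "cow") or a dict of explicit
    :class:`CowPhantom` constructor arguments (no randomisation).  The same
    (spec, seed) pair always returns an identical phantom.
    """
    if isinstance(spec, dict):
        return CowPhantom(**spec)
    if spec not in PHANTOM_PRESETS:
        raise ValueError(f"unknown phantom preset {spec!r}")
    ranges = PHANTOM_PRESETS[spec]
    rng = np.random.default_rng(seed)

    def draw(name):
        lo, hi = ranges[name]
        return float(rng.uniform(lo, hi))

    a = draw("a")
    b = draw("b_over_a") * a
    c = draw("c_over_b") * b
    zc = c + draw("belly_clearance")
    hip_x = draw("hip_x_rel") * a
    phantom_kwargs = dict(
        a=a, b=b, c=c, zc=zc,
        blend_x=-0.18 * a, blend_w=0.05 * a,
        waist_x=draw("waist_x_rel") * a,
        waist_depth=draw("waist_depth"),
        waist_sigma=draw("waist_sigma"),
        hip_x=hip_x,
        hip_amp=draw("hip_amp"),
        hip_sigma=draw("hip_sigma"),
        withers_x=0.0,  # set below: clear of the chest waist
        withers_amp=draw("withers_amp"),
        withers_sigma=draw("withers_sigma"),
        tail_x=hip_x - draw("tail_dx_rel") * a,
        tail_amp=draw("tail_amp"),
        tail_sigma=draw("tail_sigma"),
        leg_radius=draw("leg_radius"),
        front_leg_x=0.42 * a,
        rear_leg_x=hip_x,
        leg_y=0.55 * b,
        head_hx=draw("head_hx"),
        head_hy=draw("head_hy"),
        head_hz=draw("head_hz"),
        head_gap=0.12 * a,
        head_z=draw("head_z_rel") * zc,
    )
    # hip_y depends on the local half-width at hip_x
    tmp = dict(phantom_kwargs)
    stub = CowPhantom.__new__(CowPhantom)
    for k, v in tmp.items():
        object.__setattr__(stub, k, v)
    for f in fields(CowPhantom):
        if f.name not in tmp and f.name != "truth":
            object.__setattr__(stub, f.name, f.default)
    local_halfwidth = b * float(stub.section_scale(hip_x))
    hip_y = draw("hip_u") * local_halfwidth
    phantom_kwargs["hip_y"] = hip_y
    # keep the hook-bone pair clearly bimodal: apex separation 2*hip_y must
    # exceed ~2.7 bump widths or the two maxima merge on the flat rump top
    phantom_kwargs["hip_sigma"] = min(phantom_kwargs["hip_sigma"], hip_y / 1.35)
    # cap the hook-bone slope at ~0.40 so its 45-degree dropout ring stays
    # clear of the apex and its derivative stencil
    phantom_kwargs["hip_amp"] = min(
        phantom_kwargs["hip_amp"], 0.66 * phantom_kwargs["hip_sigma"])
    # keep the withers bump tail out of the chest section: at least 2.6
    # bump widths cranial of the waist minimum
    phantom_kwargs["withers_x"] = max(
        draw("withers_x_rel") * a,
        phantom_kwargs["waist_x"] + 2.6 * phantom_kwargs["withers_sigma"] + 10.0,
    )
    # hook bones are the most prominent rump feature: cap the tail-head
    # curvature at 85% of the hip-bump curvature (smoothing erodes the
    # sharper tail bump more, so the detection-time margin is larger)
    hip_curv = phantom_kwargs["hip_amp"] / phantom_kwargs["hip_sigma"] ** 2
    max_tail = 0.85 * hip_curv * phantom_kwargs["tail_sigma"] ** 2
    phantom_kwargs["tail_amp"] = min(phantom_kwargs["tail_amp"], max_tail)
    return CowPhantom(**phantom_kwargs)
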