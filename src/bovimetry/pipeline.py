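"""End-to-end pipeline: simulate -> correct -> level/segment -> filter ->
landmarks -> body parameters -> aggregate.

A single configuration seed feeds named substreams per stage, so a run is
fully deterministic; every stage decision (smoothing scale, gradient
tolerance, datum choice) is echoed in the result's log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import body_params as bp
from .calibration import CorrectionModel, apply_correction, calibrate_sensor
from .landmarks import (
    DetectionError, detect_anatomical_maxima, detect_chest_section,
    detect_head_border, detect_hoof_floor, GRADIENT_EPS,
)
from .phantom import CowPhantom, generate_cow_phantom
from .render import Posture, render_depth
from .sensor import SensorModel
from .surface_ops import (
    derivative_maps, level_frame_to_floor, register_views, segment_body,
)

logger = logging.getLogger("bovimetry.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "extract_parameters", "PipelineResult"]


@dataclass(frozen=True)
class PipelineConfig:
    """Acquisition and processing settings for one animal.

    Defaults mirror the study conditions: four views, ten repeated captures
    per body portion, 1 m working distance, substitution calibration on the
    five reference hemispheres.
    """

    preset: str | dict = "calf"
    seed: int = 0
    working_distance: float = 1000.0
    repeats: int = 10
    views: tuple[str, ...] = ("left", "right", "top", "front")
    top_threshold: float = 300.0       # segmentation height threshold, mm
    side_threshold: float = 150.0
    smoothing_scale: float = 11.0      # derivative-map Gaussian sigma, mm
    refine_scale: float = 4.0          # light smoothing for sub-pixel refinement, mm
    gradient_eps: float = GRADIENT_EPS
    girth_slab_width: float = 30.0
    calibrate: bool = True
    refine_registration: bool = False  # simulation poses are exact
    noiseless: bool = False
    # stance variation of a standing animal (session sd; per-capture jitter sd)
    posture_pitch_sd: float = 1.0      # degrees
    posture_height_sd: float = 5.0     # mm
    capture_pitch_sd: float = 0.3      # degrees
    capture_height_sd: float = 2.0     # mm

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (400.0 <= self.working_distance <= 2000.0):
            raise ValueError("working distance must lie in [400, 2000] mm")
        for v in self.views:
            if v not in ("left", "right", "top", "front"):
                raise ValueError(f"unknown view {v!r}")


@dataclass
class PipelineResult:
    aggregate: bp.BodyParameters
    repeats: list[bp.BodyParameters]
    phantom: CowPhantom
    correction: CorrectionModel
    warnings: list[str]
    log: dict


def simulate_views(phantom: CowPhantom, sensor: SensorModel, views, rng,
                   posture: Posture | None = None) -> dict[str, object]:
    """One capture cycle: every requested view with its own noise substream."""
    return {
        view: render_depth(phantom, view, sensor,
                           seed=int(rng.integers(2 ** 31)), posture=posture)
        for view in views
    }


def extract_parameters(frames: dict, config: PipelineConfig,
                       correction: CorrectionModel | None = None,
                       warn_sink: list | None = None) -> bp.BodyParameters:
    """Body parameters from one capture cycle (a dict view -> DepthFrame)."""
    warn_sink = warn_sink if warn_sink is not None else []
    if correction is not None:
        frames = {v: apply_correction(f, correction) for v, f in frames.items()}

    result = bp.BodyParameters()
    chest_x = None
    top_level = None

    if "top" in frames:
        top = frames["top"]
        z = top.heights()
        floor_frac = float((np.isfinite(z) & (z < 100.0)).mean())
        if floor_frac >= 0.05:
            top_level, _plane = level_frame_to_floor(top)
            datum = 0.0
        else:
            top_level = top
            datum = None  # resolved from the hoof-floor landmark below
        mask = segment_body(top_level, config.top_threshold)
        maps = derivative_maps(top_level, smoothing_scale=config.smoothing_scale)
        maps_fine = derivative_maps(top_level, smoothing_scale=config.refine_scale)
        lms = detect_anatomical_maxima(maps, mask, grad_eps=config.gradient_eps,
                                       refine_maps=maps_fine)

        if datum is None:
            side = frames.get("left") or frames.get("right")
            if side is None:
                raise DetectionError("no floor visible and no side view for a datum")
            z_side = side.heights()
            leg = np.isfinite(z_side) & (z_side < 150.0)  # below the trunk
            datum = detect_hoof_floor(side, leg).z
            warn_sink.append("floor shadowed; hoof-floor landmark used as datum")

        result.hip_distance = bp.hip_distance(lms["hip_left"], lms["hip_right"])
        result.body_length = bp.body_length(lms["withers"], lms["tail_head"])
        front, back, avg = bp.heights(lms["withers"], lms["hip_left"],
                                      lms["hip_right"], datum=datum)
        result.front_height, result.back_height, result.average_height = front, back, avg
        hip_mid = 0.5 * (lms["hip_left"].position[:2] + lms["hip_right"].position[:2])
        h2w = float(np.linalg.norm(lms["withers"].position[:2] - hip_mid))
        result.back_slope = bp.back_slope(front, back, h2w)
    else:
        warn_sink.append("top view missing: rump/withers parameters skipped")

    side_frame = None
    for v in ("left", "right"):
        if v in frames:
            side_frame = frames[v]
            break
    if side_frame is not None:
        try:
            smask = segment_body(side_frame, config.side_threshold,
                                 include_void=False)
            chest = detect_chest_section(side_frame, smask)
            chest_x = chest.x
        except DetectionError as exc:
            warn_sink.append(f"chest section not found: {exc}")
    else:
        warn_sink.append("no side view: chest parameters skipped")

    if chest_x is not None:
        clouds = [frames[v].to_points() for v in ("top", "left", "right")
                  if v in frames]
        merged = register_views(
            clouds, refine=config.refine_registration,
            voxel=frames[next(iter(frames))].sensor.lateral_pitch,
        )
        merged = merged[merged[:, 2] > 100.0]  # drop floor returns
        try:
            girth = bp.chest_girth(merged, chest_x, config.girth_slab_width)
            result.chest_girth = girth.perimeter
            if np.isfinite(result.average_height):
                result.depth = bp.body_depth(result.average_height,
                                             girth.vertical_extent)
        except bp.InconsistentGeometryError as exc:
            warn_sink.append(f"chest girth failed: {exc}")

    if "front" in frames:
        try:
            left_b, right_b = detect_head_border(frames["front"])
            result.head_size = bp.head_size(left_b, right_b)
        except DetectionError as exc:
            warn_sink.append(f"head border not found: {exc}")
    else:
        warn_sink.append("front view missing: head size skipped")
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Full deterministic run: phantom, calibration, repeats, aggregation."""
    master = np.random.SeedSequence(config.seed)
    s_phantom, s_calib, s_capture = master.spawn(3)

    phantom = generate_cow_phantom(
        config.preset, seed=int(s_phantom.generate_state(1)[0] % (2 ** 31)),
    )
    sensor = SensorModel.at_distance(config.working_distance)
    if config.noiseless:
        sensor = sensor.noiseless()

    if config.calibrate:
        correction = calibrate_sensor(
            sensor, seed=int(s_calib.generate_state(1)[0] % (2 ** 31)),
        )
    else:
        correction = CorrectionModel.identity()

    rng = np.random.default_rng(s_capture)
    warn_sink: list[str] = []
    per_repeat = []
    session = Posture(
        pitch_deg=float(rng.normal(0.0, config.posture_pitch_sd)),
        height_offset=float(rng.normal(0.0, config.posture_height_sd)),
    )
    for rep in range(config.repeats):
        posture = Posture(
            pitch_deg=session.pitch_deg + float(rng.normal(0.0, config.capture_pitch_sd)),
            height_offset=session.height_offset + float(rng.normal(0.0, config.capture_height_sd)),
        )
        frames = simulate_views(phantom, sensor, config.views, rng, posture)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", bp.LowCoverageWarning)
            try:
                per_repeat.append(
                    extract_parameters(frames, config, correction, warn_sink)
                )
            except DetectionError as exc:
                warn_sink.append(f"repeat {rep} dropped: {exc}")
    if len(per_repeat) < max(1, config.repeats // 2):
        raise DetectionError(
            f"only {len(per_repeat)}/{config.repeats} capture cycles usable; "
            + "; ".join(warn_sink[-3:])
        )
    aggregate = bp.aggregate_repeats(per_repeat)

    log = {
        "preset": config.preset, "seed": config.seed,
        "working_distance_mm": config.working_distance,
        "repeats": config.repeats, "views": list(config.views),
        "smoothing_scale_mm": config.smoothing_scale,
        "gradient_eps": config.gradient_eps,
        "top_threshold_mm": config.top_threshold,
        "side_threshold_mm": config.side_threshold,
        "posture_session": (session.pitch_deg, session.height_offset),
        "correction_scale": correction.scale,
        "correction_offset": correction.offset,
        "datum": "hoof_floor" if any("hoof" in w for w in warn_sink) else "floor_plane",
    }
    logger.info("pipeline finished: %s", log)
    return PipelineResult(
        aggregate=aggregate, repeats=per_repeat, phantom=phantom,
        correction=correction, warnings=warn_sink, log=log,
    )
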