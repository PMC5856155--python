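"""Synthetic reference targets, cow phantoms and the virtual depth sensor.

Facade over the sensor model (:mod:`bovimetry.sensor`), the parametric
phantom (:mod:`bovimetry.phantom`) and the renderer
(:mod:`bovimetry.render`): everything needed to produce depth captures with
known ground truth, so every downstream stage is testable without a real
camera or animal.
"""

from .phantom import (
    CowPhantom, GroundTruthParameters, generate_cow_phantom, PHANTOM_PRESETS,
)
from .render import (
    Posture, default_view_target, generate_flat_plane, generate_hemisphere,
    render_depth,
)
from .sensor import (
    DepthFrame, SensorModel, camera_pose, PERFORMANCE_TABLE, VIEWS,
)

__all__ = [
    "CowPhantom", "GroundTruthParameters", "generate_cow_phantom",
    "PHANTOM_PRESETS", "Posture", "default_view_target",
    "generate_flat_plane", "generate_hemisphere", "render_depth",
    "DepthFrame", "SensorModel", "camera_pose", "PERFORMANCE_TABLE", "VIEWS",
]
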