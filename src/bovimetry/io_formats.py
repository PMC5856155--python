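"""File formats: PLY/XYZ point clouds, PGM masks, YAML configs and models.

Depth frames are persisted as point clouds (void pixels omitted): binary
little-endian PLY via trimesh, or whitespace-delimited XYZ text.  All
coordinates are millimetres.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .calibration import CorrectionModel
from .sensor import DepthFrame

__all__ = [
    "write_ply", "read_ply", "write_xyz", "read_xyz", "frame_to_cloud",
    "write_mask_pgm", "save_correction", "load_correction",
    "save_pose", "load_pose",
]


def frame_to_cloud(frame: DepthFrame, world: bool = True) -> np.ndarray:
    """Valid pixels of a frame as an (N, 3) cloud in mm."""
    return frame.to_points(world=world)


def write_ply(points, path) -> None:
    """Binary little-endian PLY (x y z float, mm)."""
    import trimesh

    pc = trimesh.PointCloud(np.asarray(points, float))
    Path(path).write_bytes(pc.export(file_type="ply"))


def read_ply(path) -> np.ndarray:
    import trimesh

    loaded = trimesh.load(str(path), process=False)
    return np.asarray(loaded.vertices, float)


def write_xyz(points, path) -> None:
    np.savetxt(path, np.asarray(points, float), fmt="%.4f")


def read_xyz(path) -> np.ndarray:
    pts = np.loadtxt(path, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, found {pts.shape[1]}")
    return pts


def write_mask_pgm(mask, path) -> None:
    """Boolean mask as a plain-text (P2) PGM image for quick inspection."""
    m = np.asarray(mask, bool)
    with open(path, "w") as fh:
        fh.write(f"P2\n{m.shape[1]} {m.shape[0]}\n255\n")
        for row in m:
            fh.write(" ".join("255" if v else "0" for v in row) + "\n")


def save_correction(model: CorrectionModel, path) -> None:
    doc = {
        "scale": list(model.scale),
        "offset": list(model.offset),
        "provenance": [list(p) for p in model.provenance],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_correction(path) -> CorrectionModel:
    doc = yaml.safe_load(Path(path).read_text())
    return CorrectionModel(
        scale=tuple(doc["scale"]), offset=tuple(doc["offset"]),
        provenance=tuple(tuple(p) for p in doc.get("provenance", [])),
    )


def save_pose(pose: np.ndarray, path) -> None:
    """4x4 row-major rigid transform, mm, as YAML."""
    Path(path).write_text(yaml.safe_dump(
        {"matrix": np.asarray(pose, float).reshape(4, 4).tolist()},
        sort_keys=False,
    ))


def load_pose(path) -> np.ndarray:
    doc = yaml.safe_load(Path(path).read_text())
    m = np.asarray(doc["matrix"], float)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: pose must be a 4x4 matrix")
    return m
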