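"""File-format boundary: depth PNGs, calibration YAML, mesh PLY/OBJ.

Units at the boundary follow the common RGB-D dialect: depth images are
16-bit unsigned PNGs in millimeters with 0 marking invalid pixels;
poses are 4x4 row-major matrices in meters, keyed by camera id, in a
YAML calibration file.  Everything in memory is meters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .depth import CameraIntrinsics, DepthImage
from .meshes import TriMesh
from .transforms import RigidTransform

__all__ = [
    "save_depth_png",
    "load_depth_png",
    "save_rig_yaml",
    "load_rig_yaml",
    "save_mesh",
    "load_mesh",
]


def save_depth_png(path, depth: DepthImage) -> None:
    import imageio.v3 as iio

    mm = np.zeros(depth.shape, dtype=np.uint16)
    d = np.round(depth.depth * 1000.0)
    ok = depth.valid & (d >= 1) & (d <= np.iinfo(np.uint16).max)
    mm[ok] = d[ok].astype(np.uint16)
    iio.imwrite(str(path), mm)


def load_depth_png(path) -> DepthImage:
    import imageio.v3 as iio

    mm = iio.imread(str(path))
    if mm.dtype != np.uint16 or mm.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 16-bit depth PNG")
    return DepthImage(mm.astype(float) / 1000.0, mm > 0)


def _intrinsics_dict(K: CameraIntrinsics) -> dict:
    return {
        "fx": float(K.fx), "fy": float(K.fy),
        "cx": float(K.cx), "cy": float(K.cy),
        "width": int(K.width), "height": int(K.height),
    }


def save_rig_yaml(path, poses: dict, intrinsics: CameraIntrinsics | dict | None = None,
                  extra: dict | None = None) -> None:
    """Write camera poses (and optionally intrinsics) keyed by camera id."""
    doc: dict = {"cameras": {}}
    for cam_id, T in poses.items():
        entry: dict = {"pose": [[float(x) for x in row] for row in T.matrix]}
        if isinstance(intrinsics, dict):
            entry["intrinsics"] = _intrinsics_dict(intrinsics[cam_id])
        elif intrinsics is not None:
            entry["intrinsics"] = _intrinsics_dict(intrinsics)
        doc["cameras"][int(cam_id)] = entry
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_rig_yaml(path):
    """Returns ({cam_id: RigidTransform}, {cam_id: CameraIntrinsics or None})."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "cameras" not in doc:
        raise ValueError(f"{path}: not a rig calibration file")
    poses, intr = {}, {}
    for cam_id, entry in doc["cameras"].items():
        poses[int(cam_id)] = RigidTransform(np.array(entry["pose"], dtype=float))
        ki = entry.get("intrinsics")
        intr[int(cam_id)] = CameraIntrinsics(**ki) if ki else None
    return poses, intr


def save_mesh(path, mesh: TriMesh) -> None:
    tm = mesh.to_trimesh()
    if mesh.vertex_normals is not None:
        tm.vertex_normals = mesh.vertex_normals
    tm.export(str(path))


def load_mesh(path) -> TriMesh:
    import trimesh as _tm

    tm = _tm.load(str(path), force="mesh", process=False)
    mesh = TriMesh(np.asarray(tm.vertices, dtype=float),
                   np.asarray(tm.faces, dtype=np.int64))
    vn = np.asarray(tm.vertex_normals, dtype=float)
    if vn.shape == mesh.vertices.shape:
        mesh.vertex_normals = vn
    return mesh
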