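"""End-to-end orchestration: depth images -> segmented clouds -> refined
poses -> watertight mesh, with metrics and a residual trace on the way out.

The pipeline mirrors the capture-rig workflow: per-camera depth frames
plus an environment-only capture and a calibration file come in; each
frame is back-projected, triangulated and segmented; the pose-anchored
interleaved registration refines the calibrated poses; the final
surface is reconstructed from the registered clouds.  The world frame
is camera 0's calibration frame.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path


import yaml

from .depth import CameraIntrinsics, backproject, triangulate_grid
from .io import load_depth_png, load_rig_yaml, save_mesh, save_rig_yaml
from .registration import (
    Camera,
    CameraRig,
    RegistrationConfig,
    residual_metrics,
    run_interleaved,
)
from .segmentation import BackgroundIndex, SegmentationConfig, segment_animal

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "rig_from_files"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and camera id."""

    def __init__(self, stage: str, cam_id, message: str):
        super().__init__(f"[{stage}] camera {cam_id}: {message}")
        self.stage = stage
        self.cam_id = cam_id


def _from_mapping(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations plus the master seed.

    Loadable from YAML; unknown keys are rejected so typos fail loudly.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        allowed = {f.name for f in fields(cls)}
        unknown = set(doc) - allowed
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            segmentation=_from_mapping(
                SegmentationConfig, doc.get("segmentation", {}) or {}
            ),
            registration=_from_mapping(
                RegistrationConfig, doc.get("registration", {}) or {}
            ),
            seed=int(doc.get("seed", 0)),
        )


def rig_from_files(
    scene_dir,
    cfg: PipelineConfig,
    intrinsics: CameraIntrinsics | None = None,
) -> CameraRig:
    """Build a rig from ``<dir>/rig.yaml`` plus per-camera depth PNGs.

    Expects ``depth_<id>.png`` frames and ``environment_<id>.png``
    captures for every camera listed in the calibration file.
    """
    scene_dir = Path(scene_dir)
    poses, intr = load_rig_yaml(scene_dir / "rig.yaml")
    cameras = []
    for cam_id in sorted(poses):
        K = intr.get(cam_id) or intrinsics
        if K is None:
            raise PipelineError("load", cam_id, "no intrinsics available")
        frame_path = scene_dir / f"depth_{cam_id}.png"
        env_path = scene_dir / f"environment_{cam_id}.png"
        if not frame_path.exists():
            raise PipelineError("load", cam_id, f"missing frame {frame_path.name}")
        if not env_path.exists():
            raise PipelineError(
                "load", cam_id, f"missing environment capture {env_path.name}"
            )
        try:
            frame_cloud = backproject(load_depth_png(frame_path), K)
            frame_mesh = triangulate_grid(frame_cloud)
            env_cloud = backproject(load_depth_png(env_path), K)
            bg = BackgroundIndex(
                env_cloud.valid_points(),
                radius=cfg.segmentation.background_radius,
            )
            animal = segment_animal(frame_mesh, bg, cfg.segmentation)
        except Exception as exc:
            raise PipelineError("segment", cam_id, str(exc)) from exc
        log.info("[segment] camera %s: %d animal vertices", cam_id,
                 animal.n_vertices)
        cameras.append(
            Camera(
                cam_id=cam_id,
                T_init=poses[cam_id],
                points=animal.vertices,
                normals=animal.vertex_normals,
            )
        )
    return CameraRig(cameras)


def run_pipeline(
    rig: CameraRig,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir=None,
):
    """Register the rig, reconstruct the final surface, write artifacts.

    Returns (result, metrics dict).  With ``out_dir`` set, writes
    ``mesh.ply``, ``poses.yaml``, ``trace.csv`` and ``metrics.json``.
    """
    try:
        result = run_interleaved(rig, cfg.registration)
    except Exception as exc:
        raise PipelineError("register", "all", str(exc)) from exc

    metrics_rt = residual_metrics(
        rig, result.mesh, overlap=result.overlap, cfg=cfg.registration
    )
    metrics = {
        "iterations": result.iterations,
        "converged": result.converged,
        "residual_trace_mm": [round(x, 6) for x in result.residual_trace_mm],
        "final_point_to_plane_mm": metrics_rt.point_to_plane_mm,
        "final_point_to_point_mm": metrics_rt.point_to_point_mm,
        "mesh_vertices": result.mesh.n_vertices,
        "mesh_triangles": result.mesh.n_triangles,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_mesh(out_dir / "mesh.ply", result.mesh)
        save_rig_yaml(
            out_dir / "poses.yaml",
            {c.cam_id: T for c, T in zip(rig.cameras, result.poses)},
        )
        with open(out_dir / "trace.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "point_to_plane_mm"])
            for i, v in enumerate(result.residual_trace_mm, start=1):
                w.writerow([i, f"{v:.6f}"])
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return result, metrics
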