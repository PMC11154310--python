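"""Pose-set evaluation against ground truth.

A multi-camera registration anchored only by soft pose priors recovers
the *relative* camera geometry; the absolute (gauge) placement is set by
the average of the priors and is not informative about alignment
quality.  Pose errors are therefore reported after removing the global
gauge: a single rigid transform G, fitted in closed form, maps the
estimated camera set onto the true one (chordal-mean rotation over the
per-camera corrections, then least-squares translation on the camera
centers).  Raw errors are available with ``align_gauge=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import RigidTransform, _nearest_rotation, rotation_angle_deg

__all__ = ["PoseErrors", "pose_set_error", "fit_gauge"]


@dataclass(frozen=True)
class PoseErrors:
    rotation_deg: np.ndarray  # per camera
    translation_m: np.ndarray  # per camera
    gauge: RigidTransform

    @property
    def mean_rotation_deg(self) -> float:
        return float(self.rotation_deg.mean())

    @property
    def mean_translation_mm(self) -> float:
        return float(self.translation_m.mean() * 1000.0)


def fit_gauge(estimated, truth) -> RigidTransform:
    """Closed-form rigid G aligning the estimated camera set to the true one.

    The rotation comes from the Kabsch fit on the camera centers (the
    absolute-trajectory-error convention), which is well conditioned for
    a ring of cameras; if the centers are nearly degenerate (collinear),
    it falls back to the chordal mean of the per-camera orientation
    corrections.
    """
    c_est = np.stack([e.translation for e in estimated])
    c_true = np.stack([t.translation for t in truth])
    h = (c_est - c_est.mean(axis=0)).T @ (c_true - c_true.mean(axis=0))
    u, s, vt = np.linalg.svd(h)
    if s[1] > 1e-9 * max(s[0], 1.0):  # centers span at least a plane
        d = np.sign(np.linalg.det(vt.T @ u.T))
        R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    else:
        R_corr = sum(t.rotation @ e.rotation.T for e, t in zip(estimated, truth))
        R = _nearest_rotation(np.asarray(R_corr, dtype=float))
    t = c_true.mean(axis=0) - R @ c_est.mean(axis=0)
    return RigidTransform.from_rotation_translation(R, t)


def pose_set_error(estimated, truth, align_gauge: bool = True) -> PoseErrors:
    """Per-camera rotation (deg) and translation (m) errors vs ground truth."""
    if len(estimated) != len(truth):
        raise ValueError("pose lists must have equal length")
    gauge = (
        fit_gauge(estimated, truth) if align_gauge else RigidTransform.identity()
    )
    aligned = [gauge @ e for e in estimated]
    rot = np.array(
        [rotation_angle_deg(a.rotation, t.rotation) for a, t in zip(aligned, truth)]
    )
    tr = np.array(
        [
            np.linalg.norm(a.translation - t.translation)
            for a, t in zip(aligned, truth)
        ]
    )
    return PoseErrors(rotation_deg=rot, translation_m=tr, gauge=gauge)
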