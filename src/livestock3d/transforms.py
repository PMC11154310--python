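"""Rigid-transform algebra and the small-angle pose parameterization.

A camera pose is a 4x4 homogeneous transform mapping camera-frame points
into the world frame (meters).  During optimization a pose update is
parameterized by a 6-vector ``xi = (alpha, beta, gamma, t0, t1, t2)``:
rotations (radians) about the x, y and z axes and a translation (meters).
For small angles the updated pose is approximated by the linear matrix

    L(xi) = [[ 1, -g,  b, t0],
             [ g,  1, -a, t1],
             [-b,  a,  1, t2],
             [ 0,  0,  0,  1]]

i.e. ``I + skew((a, b, g))`` in the rotation block.  The same
parameterization, applied to the relative transform ``inv(T0) @ T``,
yields the pose-anchor regularizer

    Gamma(T, T0) = kr * (a^2 + b^2 + g^2) + kt * (t0^2 + t1^2 + t2^2)

which penalizes a camera for drifting from its calibrated pose and pins
down the global gauge of the multi-camera objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "PoseIncrement",
    "RegularizerWeights",
    "increment_matrix",
    "apply_increment",
    "extract_increment",
    "gamma",
    "rigid_from_correspondences",
    "rotation_angle_deg",
]

_ORTHO_TOL = 1e-9


def _nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix to the nearest rotation (polar/SVD projection)."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


class RigidTransform:
    """A 4x4 homogeneous rigid transform; rotation block orthonormal, det +1."""

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite entries in transform")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row must be exactly (0, 0, 0, 1)")
        r = m[:3, :3]
        if np.abs(r @ r.T - np.eye(3)).max() > 1e-6 or np.linalg.det(r) < 0:
            raise ValueError("rotation block not orthonormal with det +1")
        # snap tiny numerical drift so the invariant holds to 1e-9
        if np.abs(r @ r.T - np.eye(3)).max() > _ORTHO_TOL:
            m = m.copy()
            m[:3, :3] = _nearest_rotation(r)
        self.matrix = m
        self.matrix.flags.writeable = False

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = -r @ self.translation
        return RigidTransform(m)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        m = self.matrix @ other.matrix
        m[3] = (0.0, 0.0, 0.0, 1.0)
        m[:3, :3] = _nearest_rotation(m[:3, :3])
        return RigidTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return bool(np.abs(self.matrix - other.matrix).max() <= tol)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RigidTransform(t={self.translation}, R=\n{self.rotation})"


@dataclass(frozen=True)
class PoseIncrement:
    """Small pose update: rotations about x/y/z (rad) and a translation (m).

    The linearization is intended for |angle| below roughly 0.06 rad (~3 deg).
    """

    alpha: float
    beta: float
    gamma: float
    t0: float
    t1: float
    t2: float

    def __post_init__(self):
        v = self.as_array()
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite pose increment")

    @classmethod
    def zero(cls) -> "PoseIncrement":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, v) -> "PoseIncrement":
        v = np.asarray(v, dtype=float)
        if v.shape != (6,):
            raise ValueError("pose increment must have 6 components")
        return cls(*v.tolist())

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta, self.gamma, self.t0, self.t1, self.t2]
        )

    @property
    def rotation_params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def translation_params(self) -> np.ndarray:
        return np.array([self.t0, self.t1, self.t2])


@dataclass(frozen=True)
class RegularizerWeights:
    """Weights of the pose anchor: kr on squared radians, kt on squared meters."""

    kr: float
    kt: float

    def __post_init__(self):
        if not (self.kr >= 0 and self.kt >= 0):
            raise ValueError("regularizer weights must be non-negative")


def increment_matrix(xi: PoseIncrement) -> np.ndarray:
    """The linearized update matrix L(xi) = [[I + skew(angles), t], [0, 1]]."""
    a, b, g = xi.alpha, xi.beta, xi.gamma
    return np.array(
        [
            [1.0, -g, b, xi.t0],
            [g, 1.0, -a, xi.t1],
            [-b, a, 1.0, xi.t2],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def apply_increment(xi: PoseIncrement, T: RigidTransform) -> RigidTransform:
    """Return L(xi) @ T with the rotation block re-projected onto SO(3).

    The linear matrix L(xi) is not exactly orthogonal; projecting to the
    nearest rotation after every update keeps drift from accumulating over
    the outer iterations.
    """
    m = increment_matrix(xi) @ T.matrix
    m[3] = (0.0, 0.0, 0.0, 1.0)
    m[:3, :3] = _nearest_rotation(m[:3, :3])
    return RigidTransform(m)


def extract_increment(T_rel: RigidTransform) -> PoseIncrement:
    """Invert the small-angle linearization on a near-identity transform.

    Translations are read directly; rotation parameters come from the
    antisymmetric part (R - R^T)/2, matching the skew pattern of L(xi).
    Raises if the rotation is too far from identity (trace < 2.8, roughly
    10 degrees) for the linearization to be meaningful.
    """
    r = T_rel.rotation
    tr = float(np.trace(r))
    if tr < 2.8:
        raise ValueError(
            f"rotation too far from identity for linearization (trace={tr:.3f})"
        )
    a_part = 0.5 * (r - r.T)
    return PoseIncrement(
        alpha=float(a_part[2, 1]),
        beta=float(a_part[0, 2]),
        gamma=float(a_part[1, 0]),
        t0=float(T_rel.translation[0]),
        t1=float(T_rel.translation[1]),
        t2=float(T_rel.translation[2]),
    )


def gamma(
    Ti: RigidTransform, Ti0: RigidTransform, w: RegularizerWeights
) -> float:
    """Pose-anchor penalty Gamma = kr * sum(r^2) + kt * sum(t^2).

    Computed from the relative transform inv(Ti0) @ Ti expressed in the
    initial camera's frame.  Zero iff Ti equals Ti0.
    """
    xi = extract_increment(Ti0.inverse() @ Ti)
    return float(
        w.kr * np.sum(xi.rotation_params**2)
        + w.kt * np.sum(xi.translation_params**2)
    )


def rigid_from_correspondences(a: np.ndarray, b: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping points b onto a.

    Kabsch scheme: centroid alignment plus rotation from the SVD of the
    cross-covariance, with the determinant sign fixed to +1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 3:
        raise ValueError("need matching (n>=3, 3) point arrays")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    t = ca - r @ cb
    return RigidTransform.from_rotation_translation(r, t)


def rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray | None = None) -> float:
    """Geodesic angle (degrees) of Ra, or between Ra and Rb if given."""
    r = Ra if Rb is None else Ra @ np.asarray(Rb).T
    c = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))
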