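"""Sphere-target extrinsic calibration.

A rig of spheres with mutually distinct pairwise center distances is
captured by every camera.  Each camera fits the visible sphere centers
in its own frame; because the distance pattern is unique, center
correspondence between two cameras follows from matching the pairwise
distance multisets, and the rigid transform between the cameras is then
the closed-form Kabsch least-squares fit on the matched centers.
Chaining pairwise transforms to a reference camera (camera 0 = world)
produces the initial poses the registration stage refines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares

from .transforms import RigidTransform, rigid_from_correspondences

__all__ = [
    "SphereObservation",
    "fit_sphere",
    "match_centers_by_distances",
    "register_sphere_rig",
    "chain_calibration",
]

DISTANCE_MATCH_TOL = 0.005  # 5 mm


@dataclass(frozen=True)
class SphereObservation:
    """A fitted calibration sphere in one camera's frame."""

    center: np.ndarray  # (3,) meters
    radius: float
    inliers: int

    def __post_init__(self):
        if not (0.01 < self.radius < 0.5):
            raise ValueError(
                f"implausible sphere radius {self.radius:.3f} m "
                "(expected between 0.01 and 0.5)"
            )
        if self.inliers < 10:
            raise ValueError("sphere fit needs at least 10 supporting points")


def fit_sphere(points: np.ndarray) -> SphereObservation:
    """Least-squares sphere fit: algebraic seed, then geometric refinement.

    The algebraic step linearizes |p|^2 = 2 c . p + (r^2 - |c|^2) and is
    exact on noiseless data; geometric refinement minimizes the radial
    residual | |p - c| - r |.  Fewer than 4 points, or a coplanar set,
    cannot determine a sphere and raise.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(p) < 4:
        raise ValueError("sphere fit requires at least 4 points")
    A = np.concatenate([2.0 * p, np.ones((len(p), 1))], axis=1)
    rhs = np.einsum("ij,ij->i", p, p)
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 4:
        raise ValueError("points are coplanar: sphere is undetermined")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate sphere fit (non-positive radius)")
    radius = float(np.sqrt(r2))

    def residual(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    refined = least_squares(residual, np.append(center, radius), method="lm")
    center, radius = refined.x[:3], float(refined.x[3])
    return SphereObservation(center=center, radius=radius, inliers=len(p))


def _pairwise_distances(centers: np.ndarray):
    pairs = list(combinations(range(len(centers)), 2))
    d = np.array(
        [np.linalg.norm(centers[i] - centers[j]) for i, j in pairs]
    )
    return pairs, d


def _check_distinct(d: np.ndarray, tol: float, label: str):
    ds = np.sort(d)
    gaps = np.diff(ds)
    if len(gaps) and gaps.min() <= tol:
        k = int(np.argmin(gaps))
        raise ValueError(
            f"ambiguous sphere rig in {label}: two pairwise distances "
            f"({ds[k]:.4f} m and {ds[k + 1]:.4f} m) within the matching "
            f"tolerance {tol:.4f} m"
        )


def match_centers_by_distances(
    centers_a: np.ndarray,
    centers_b: np.ndarray,
    tol: float = DISTANCE_MATCH_TOL,
):
    """Correspondence (idx_a, idx_b) from matching pairwise-distance multisets.

    Each center is characterized by the multiset of its distances to the
    other centers of the same camera; a center in b corresponds to the
    center in a sharing the most distances within tolerance.  Requires all
    distances within each camera to be mutually distinct by more than the
    tolerance, otherwise the pattern is ambiguous.
    """
    a = np.asarray(centers_a, dtype=float).reshape(-1, 3)
    b = np.asarray(centers_b, dtype=float).reshape(-1, 3)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 sphere centers per camera")
    pairs_a, da = _pairwise_distances(a)
    pairs_b, db = _pairwise_distances(b)
    _check_distinct(da, tol, "camera a")
    _check_distinct(db, tol, "camera b")

    # votes[i, k]: how many of i's incident distances appear among k's
    votes = np.zeros((len(a), len(b)), dtype=int)
    for (i, j), dij in zip(pairs_a, da):
        for (k, l), dkl in zip(pairs_b, db):
            if abs(dij - dkl) <= tol:
                # matched distance: endpoints correspond as {i,j} <-> {k,l};
                # orientation resolved by majority voting over all matches
                votes[i, k] += 1
                votes[i, l] += 1
                votes[j, k] += 1
                votes[j, l] += 1

    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-votes)
    matched = [(int(i), int(k)) for i, k in zip(rows, cols) if votes[i, k] >= 2]
    if len(matched) < 3:
        raise ValueError(
            f"only {len(matched)} sphere correspondences found; need >= 3"
        )
    return matched


def register_sphere_rig(
    centers_a: np.ndarray,
    centers_b: np.ndarray,
    tol: float = DISTANCE_MATCH_TOL,
) -> RigidTransform:
    """Rigid transform mapping camera-b frame into camera-a frame.

    Correspondence via distance-multiset matching, then the closed-form
    Kabsch fit on the matched centers.
    """
    a = np.asarray(centers_a, dtype=float).reshape(-1, 3)
    b = np.asarray(centers_b, dtype=float).reshape(-1, 3)
    matched = match_centers_by_distances(a, b, tol=tol)
    ia = [m[0] for m in matched]
    ib = [m[1] for m in matched]
    return rigid_from_correspondences(a[ia], b[ib])


def chain_calibration(
    centers_per_camera: list, tol: float = DISTANCE_MATCH_TOL
) -> list[RigidTransform]:
    """Initial poses for all cameras by chaining pairwise calibrations.

    Camera 0 defines the world frame; camera i's pose is the composition
    of the pairwise transforms along the chain 0-1-...-i.  Residual chain
    error is corrected downstream by the pose-anchored registration.
    """
    if len(centers_per_camera) < 2:
        raise ValueError("need at least two cameras to calibrate")
    poses = [RigidTransform.identity()]
    for i in range(1, len(centers_per_camera)):
        pair = register_sphere_rig(
            centers_per_camera[i - 1], centers_per_camera[i], tol=tol
        )
        poses.append(poses[i - 1] @ pair)
    return poses
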