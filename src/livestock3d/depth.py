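"""Depth-image ingestion: back-projection and grid triangulation.

A 16-bit depth image (millimeters, 0 = invalid at the file boundary;
meters in memory) is back-projected through the pinhole model into an
*organized* point cloud that keeps the pixel-grid layout.  Adjacent
valid pixels are then stitched into counter-clockwise triangles, and
each vertex normal is the normalized average of its incident triangle
normals — the per-camera mesh the segmentation stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshes import TriMesh

__all__ = [
    "CameraIntrinsics",
    "DepthImage",
    "OrganizedCloud",
    "backproject",
    "project",
    "triangulate_grid",
]

DEPTH_MIN_M = 0.1
DEPTH_MAX_M = 20.0
DEGENERATE_AREA_M2 = 1e-12


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")

    @classmethod
    def from_fov(
        cls, width: int, height: int, hfov_deg: float = 69.4
    ) -> "CameraIntrinsics":
        """Square-pixel intrinsics from a horizontal field of view."""
        fx = width / (2.0 * np.tan(np.radians(hfov_deg) / 2.0))
        return cls(fx=fx, fy=fx, cx=width / 2.0, cy=height / 2.0,
                   width=width, height=height)

    def scaled(self, width: int, height: int) -> "CameraIntrinsics":
        sx, sy = width / self.width, height / self.height
        return CameraIntrinsics(
            self.fx * sx, self.fy * sy, self.cx * sx, self.cy * sy, width, height
        )


@dataclass
class DepthImage:
    """Per-pixel depth in meters with a validity mask."""

    depth: np.ndarray  # (h, w) float meters
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("depth must be a 2D grid")
        finite = np.isfinite(self.depth)
        in_range = finite & (self.depth > DEPTH_MIN_M) & (self.depth < DEPTH_MAX_M)
        if self.valid is None:
            self.valid = in_range
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & in_range
        if self.valid.shape != self.depth.shape:
            raise ValueError("mask shape must match depth shape")

    @property
    def shape(self):
        return self.depth.shape


@dataclass
class OrganizedCloud:
    """Per-pixel camera-frame points on the image grid, plus validity.

    ``points[v, u]`` back-projects from pixel ``(u, v)``.  Normals are
    filled in by :func:`triangulate_grid` and oriented toward the camera
    center (negative z component in the camera frame).
    """

    points: np.ndarray  # (h, w, 3)
    valid: np.ndarray  # (h, w)
    normals: np.ndarray | None = None  # (h, w, 3)
    # filled by triangulate_grid: mesh vertex index per pixel, -1 if unused
    vertex_of_pixel: np.ndarray | None = None

    @property
    def shape(self):
        return self.valid.shape

    def valid_points(self) -> np.ndarray:
        return self.points[self.valid]


def backproject(depth: DepthImage, K: CameraIntrinsics) -> OrganizedCloud:
    """Back-project a depth grid through the pinhole model.

    x = (u - cx) * z / fx, y = (v - cy) * z / fy; invalid pixels stay masked.
    """
    h, w = depth.shape
    if (h, w) != (K.height, K.width):
        raise ValueError(
            f"depth shape {(h, w)} does not match intrinsics {(K.height, K.width)}"
        )
    u = np.arange(w)[None, :]
    v = np.arange(h)[:, None]
    z = depth.depth
    pts = np.empty((h, w, 3))
    pts[..., 0] = (u - K.cx) * z / K.fx
    pts[..., 1] = (v - K.cy) * z / K.fy
    pts[..., 2] = z
    pts[~depth.valid] = np.nan
    return OrganizedCloud(points=pts, valid=depth.valid.copy())


def project(points: np.ndarray, K: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection of camera-frame points to (u, v) pixel coords."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    z = p[:, 2]
    return np.stack([K.fx * p[:, 0] / z + K.cx, K.fy * p[:, 1] / z + K.cy], axis=1)


def triangulate_grid(cloud: OrganizedCloud) -> TriMesh:
    """Stitch an organized cloud into a triangle mesh with vertex normals.

    Every 2x2 pixel cell whose four corners are valid yields two triangles
    split along a fixed diagonal: (v,u)-(v+1,u)-(v,u+1) and
    (v+1,u)-(v+1,u+1)-(v,u+1).  Triangles whose 3D corners are collinear
    (area below 1e-12 m^2) are skipped.  The winding makes triangle
    normals point toward the camera; each vertex normal is the normalized
    average of its incident triangle normals.
    """
    h, w = cloud.shape
    valid = cloud.valid
    if h < 2 or w < 2 or not valid.any():
        return _empty_mesh()

    flat_index = np.arange(h * w).reshape(h, w)
    cell = (
        valid[:-1, :-1] & valid[1:, :-1] & valid[:-1, 1:] & valid[1:, 1:]
    )
    if not cell.any():
        return _empty_mesh()

    i00 = flat_index[:-1, :-1][cell]  # (v, u)
    i10 = flat_index[1:, :-1][cell]  # (v+1, u)
    i01 = flat_index[:-1, 1:][cell]  # (v, u+1)
    i11 = flat_index[1:, 1:][cell]  # (v+1, u+1)

    tris = np.concatenate(
        [
            np.stack([i00, i10, i01], axis=1),
            np.stack([i10, i11, i01], axis=1),
        ]
    )

    pts_flat = cloud.points.reshape(-1, 3)
    a = pts_flat[tris[:, 0]]
    b = pts_flat[tris[:, 1]]
    c = pts_flat[tris[:, 2]]
    cross = np.cross(b - a, c - a)
    area2 = np.linalg.norm(cross, axis=1)  # twice the area
    keep = area2 > 2.0 * DEGENERATE_AREA_M2
    tris = tris[keep]
    if len(tris) == 0:
        return _empty_mesh()
    tri_normals = cross[keep] / area2[keep][:, None]

    # vertex normal = normalized mean of incident triangle normals
    acc = np.zeros((h * w, 3))
    cnt = np.zeros(h * w)
    for k in range(3):
        np.add.at(acc, tris[:, k], tri_normals)
        np.add.at(cnt, tris[:, k], 1.0)
    used = np.flatnonzero(cnt > 0)
    vn = acc[used] / cnt[used][:, None]
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    vn = vn / norms

    remap = -np.ones(h * w, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TriMesh(pts_flat[used], remap[tris], vn)
    cloud.vertex_of_pixel = remap.reshape(h, w)

    # record normals back onto the organized grid for downstream use
    grid_normals = np.full((h * w, 3), np.nan)
    grid_normals[used] = vn
    cloud.normals = grid_normals.reshape(h, w, 3)
    return mesh


def _empty_mesh() -> TriMesh:
    return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), np.zeros((0, 3)))
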