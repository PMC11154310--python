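"""Synthetic multi-camera farm scene with ground truth.

Stands in for the physical capture rig: a parametric animal-like body
(superellipsoid torso, capsule legs/neck, ellipsoid head, smooth random
surface displacement) standing on a floor between two fences of vertical
bars, observed by a ring of cameras aimed at the body centroid.  Depth
is rendered by first-hit z-buffer rasterization with per-pixel
animal/environment labels, then degraded with Gaussian depth noise and
random dropout; initial pose estimates are the true poses composed with
bounded uniform perturbations.  Everything is deterministic given the
seed, and every other module's tests draw their ground truth from here.

The world frame is z-up with the floor at z = 0 and the animal centered
above the origin.  Camera frames follow the usual pinhole convention
(x right, y down, z forward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.measure import marching_cubes

from ._raster import rasterize_depth
from .depth import CameraIntrinsics, DepthImage, backproject, triangulate_grid
from .meshes import TriMesh
from .registration import Camera, CameraRig
from .segmentation import BackgroundIndex, SegmentationConfig, segment_animal
from .transforms import RigidTransform

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "render_depth",
    "perturb_and_degrade",
    "build_camera",
    "environment_cloud",
]

LABEL_ENVIRONMENT = 0
LABEL_ANIMAL = 1


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of the synthetic farm rig (meters, degrees)."""

    n_cameras: int = 10
    ring_radius: float = 2.6
    camera_height: float = 1.7
    body_length: float = 2.0
    body_height: float = 1.35  # top of the torso above the floor
    fence_offset: float = 1.35  # fences at y = +/- offset
    fence_bar_width: float = 0.05
    fence_spacing: float = 0.4
    fence_height: float = 1.6
    floor_half_extent: float = 3.5
    surface_noise_amp: float = 0.004
    animal_voxel: float = 0.02
    width: int = 1280
    height: int = 720
    hfov_deg: float = 69.4

    def __post_init__(self):
        if self.n_cameras < 2:
            raise ValueError("need at least 2 cameras")
        if self.ring_radius <= self.body_length / 2:
            raise ValueError("camera ring must clear the animal")
        if self.fence_spacing <= self.fence_bar_width:
            raise ValueError("fence bars must not touch")

    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics.from_fov(self.width, self.height, self.hfov_deg)


@dataclass
class SceneTruth:
    """Ground truth: meshes, true camera poses, per-vertex labels, seed."""

    animal: TriMesh
    environment: TriMesh
    poses: list  # true camera poses (camera -> world)
    config: SceneConfig
    seed: int
    centroid: np.ndarray = field(init=False)

    def __post_init__(self):
        self.centroid = self.animal.vertices.mean(axis=0)

    def combined(self):
        """Triangle soup + per-triangle labels for rendering."""
        na = self.animal.n_vertices
        verts = np.concatenate([self.animal.vertices, self.environment.vertices])
        tris = np.concatenate([self.animal.triangles, self.environment.triangles + na])
        labels = np.concatenate(
            [
                np.full(self.animal.n_triangles, LABEL_ANIMAL, dtype=np.int16),
                np.full(self.environment.n_triangles, LABEL_ENVIRONMENT, dtype=np.int16),
            ]
        )
        return verts, tris, labels


# ---------------------------------------------------------------------------
# animal body
# ---------------------------------------------------------------------------


def _capsule_sdf(q, a, b, r):
    ab = b - a
    t = np.clip(((q - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(q - closest, axis=1) - r


def _animal_field(q: np.ndarray, cfg: SceneConfig) -> np.ndarray:
    """Approximate signed distance of the animal body (negative inside)."""
    L = cfg.body_length
    half = np.array([0.5 * L, 0.19 * L, 0.225 * L])
    torso_c = np.array([0.0, 0.0, cfg.body_height - half[2]])
    e = 2.5
    rel = (q - torso_c) / half
    torso = (np.sum(np.abs(rel) ** e, axis=1) ** (1.0 / e) - 1.0) * half.min()

    parts = [torso]
    leg_r = 0.045 * L
    for sx in (-0.31 * L, 0.31 * L):
        for sy in (-0.11 * L, 0.11 * L):
            top = np.array([sx, sy, 0.45 * cfg.body_height])
            bottom = np.array([sx, sy, 0.0])
            parts.append(_capsule_sdf(q, top, bottom, leg_r))
    neck_a = np.array([0.46 * L, 0.0, 0.88 * cfg.body_height])
    neck_b = np.array([0.72 * L, 0.0, 1.15 * cfg.body_height])
    parts.append(_capsule_sdf(q, neck_a, neck_b, 0.065 * L))
    head_c = neck_b + np.array([0.09 * L, 0.0, 0.02 * L])
    head_half = np.array([0.12 * L, 0.06 * L, 0.07 * L])
    rel_h = (q - head_c) / head_half
    parts.append((np.linalg.norm(rel_h, axis=1) - 1.0) * head_half.min())
    return np.min(np.stack(parts), axis=0)


def _mesh_from_field(fn, bb_min, bb_max, voxel) -> TriMesh:
    dims = np.ceil((bb_max - bb_min) / voxel).astype(int) + 1
    axes = [bb_min[i] + voxel * np.arange(dims[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    vals = fn(grid.reshape(-1, 3)).reshape(grid.shape[:3])
    verts, faces, vnorm, _ = marching_cubes(
        vals, level=0.0, spacing=(voxel, voxel, voxel),
        gradient_direction="ascent",
    )
    verts = verts + bb_min
    vnorm = -vnorm  # outward for a positive-outside field
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    flip = np.einsum("ij,ij->i", np.cross(b - a, c - a), vnorm[faces].mean(axis=1)) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, ::-1]
    vn = vnorm / np.maximum(np.linalg.norm(vnorm, axis=1, keepdims=True), 1e-12)
    return TriMesh(verts, faces.astype(np.int64), vn)


def _smooth_displacement(verts: np.ndarray, amp: float, rng) -> np.ndarray:
    """Smooth random displacement: superposed long-wavelength 3D sinusoids.

    Wavelengths are of body scale (roughly 1-3 m), warping the parametric
    body into an irregular organic shape without introducing sharp local
    relief; amplitude is set by ``surface_noise_amp``.
    """
    s = np.zeros(len(verts))
    for _ in range(6):
        freq = rng.uniform(2.0, 6.0) * _random_unit(rng)
        phase = rng.uniform(0, 2 * np.pi)
        s += rng.uniform(0.5, 1.0) * np.sin(verts @ freq + phase)
    s /= max(s.std(), 1e-9)
    return amp * s


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _build_animal(cfg: SceneConfig, rng) -> TriMesh:
    pad = 4 * cfg.animal_voxel
    bb_min = np.array([-0.95 * cfg.body_length, -0.35 * cfg.body_length, -pad])
    bb_max = np.array(
        [0.95 * cfg.body_length, 0.35 * cfg.body_length, 1.15 * cfg.body_height + 0.3]
    )
    mesh = _mesh_from_field(
        lambda q: _animal_field(q, cfg), bb_min - pad, bb_max + pad, cfg.animal_voxel
    )
    if cfg.surface_noise_amp > 0:
        disp = _smooth_displacement(mesh.vertices, cfg.surface_noise_amp, rng)
        mesh = TriMesh(
            mesh.vertices + disp[:, None] * mesh.vertex_normals,
            mesh.triangles,
            mesh.vertex_normals,
        )
    return mesh


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def _box(center, half) -> TriMesh:
    import trimesh as _tm

    b = _tm.creation.box(extents=2.0 * np.asarray(half))
    b.apply_translation(center)
    return TriMesh(np.array(b.vertices), np.array(b.faces))


def _merge(meshes) -> TriMesh:
    verts, tris, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        tris.append(m.triangles + off)
        off += m.n_vertices
    return TriMesh(np.concatenate(verts), np.concatenate(tris))


def _build_environment(cfg: SceneConfig) -> TriMesh:
    s = cfg.floor_half_extent
    floor = TriMesh(
        [[-s, -s, 0], [s, -s, 0], [s, s, 0], [-s, s, 0]],
        [[0, 1, 2], [0, 2, 3]],
    )
    parts = [floor]
    xs = np.arange(-2.0, 2.0 + 1e-9, cfg.fence_spacing)
    for side in (-1.0, 1.0):
        for x in xs:
            parts.append(
                _box(
                    [x, side * cfg.fence_offset, cfg.fence_height / 2.0],
                    [cfg.fence_bar_width / 2.0, cfg.fence_bar_width / 2.0,
                     cfg.fence_height / 2.0],
                )
            )
    return _merge(parts)


# ---------------------------------------------------------------------------
# cameras and rendering
# ---------------------------------------------------------------------------


def _look_at(position, target) -> RigidTransform:
    z = np.asarray(target, dtype=float) - position
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, up)
    nx = np.linalg.norm(x)
    if nx < 1e-9:  # straight down: pick x along world x
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / nx
    y = np.cross(z, x)
    r = np.stack([x, y, z], axis=1)
    return RigidTransform.from_rotation_translation(r, position)


def generate_scene(cfg: SceneConfig = SceneConfig(), seed: int = 0) -> SceneTruth:
    """Deterministic scene: animal, environment, ring of true camera poses."""
    rng = np.random.default_rng(seed)
    animal = _build_animal(cfg, rng)
    env = _build_environment(cfg)
    target = animal.vertices.mean(axis=0)
    poses = []
    for k in range(cfg.n_cameras):
        ang = 2.0 * np.pi * k / cfg.n_cameras
        pos = np.array(
            [cfg.ring_radius * np.cos(ang), cfg.ring_radius * np.sin(ang),
             cfg.camera_height]
        )
        poses.append(_look_at(pos, target))
    return SceneTruth(animal=animal, environment=env, poses=poses,
                      config=cfg, seed=seed)


def render_depth(
    scene: SceneTruth,
    cam_index: int,
    K: CameraIntrinsics | None = None,
    include_animal: bool = True,
):
    """First-hit depth (meters) and per-pixel labels for one camera.

    Fence bars in front of the animal occlude it exactly as a ray caster
    would resolve the first intersection.  ``include_animal=False``
    renders the environment-only capture used for background subtraction.
    """
    if not 0 <= cam_index < len(scene.poses):
        raise IndexError("camera index out of range")
    K = K or scene.config.intrinsics()
    if include_animal:
        verts, tris, labels = scene.combined()
    else:
        verts = scene.environment.vertices
        tris = scene.environment.triangles
        labels = np.full(len(tris), LABEL_ENVIRONMENT, dtype=np.int16)
    cam_from_world = scene.poses[cam_index].inverse()
    v_cam = cam_from_world.apply(verts)
    tri_pts = v_cam[tris]  # (m, 3, 3)
    depth, label = rasterize_depth(
        tri_pts, labels, K.fx, K.fy, K.cx, K.cy, K.width, K.height
    )
    depth = np.where(np.isfinite(depth), depth, 0.0)
    return DepthImage(depth), label


def _degrade(depth: DepthImage, sigma: float, dropout: float, rng) -> DepthImage:
    d = depth.depth.copy()
    valid = depth.valid.copy()
    if sigma > 0:
        d[valid] += rng.normal(0.0, sigma, size=int(valid.sum()))
    if dropout > 0:
        drop = rng.random(valid.shape) < dropout
        valid &= ~drop
    d[~valid] = 0.0
    return DepthImage(d, valid)


def build_camera(
    scene: SceneTruth,
    cam_index: int,
    K: CameraIntrinsics,
    depth_sigma: float = 0.0,
    dropout: float = 0.0,
    rng=None,
    segmentation: str = "labels",
    seg_cfg: SegmentationConfig = SegmentationConfig(),
):
    """Segmented camera-frame cloud (points + normals) for one camera.

    ``segmentation='labels'`` selects animal vertices by the rendered
    ground-truth pixel labels; ``'pipeline'`` runs the actual
    background-subtraction segmentation against an environment render.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    depth, label = render_depth(scene, cam_index, K)
    depth = _degrade(depth, depth_sigma, dropout, rng)
    cloud = backproject(depth, K)
    mesh = triangulate_grid(cloud)
    if mesh.is_empty():
        raise RuntimeError(f"camera {cam_index} sees nothing")
    if segmentation == "labels":
        vert_label = np.full(mesh.n_vertices, -1, dtype=np.int16)
        vp = cloud.vertex_of_pixel
        px = vp >= 0
        vert_label[vp[px]] = label[px]
        animal = mesh.remove_vertices(vert_label != 1)
    elif segmentation == "pipeline":
        env_depth, _ = render_depth(scene, cam_index, K, include_animal=False)
        env_depth = _degrade(env_depth, depth_sigma, dropout, rng)
        env_cloud = backproject(env_depth, K)
        bg = BackgroundIndex(
            env_cloud.valid_points(), radius=seg_cfg.background_radius
        )
        animal = segment_animal(mesh, bg, seg_cfg)
    else:
        raise ValueError(f"unknown segmentation mode {segmentation!r}")
    if animal.is_empty():
        raise RuntimeError(f"camera {cam_index} sees no animal surface")
    return animal


def environment_cloud(
    scene: SceneTruth,
    cam_index: int,
    K: CameraIntrinsics,
    depth_sigma: float = 0.0,
    rng=None,
):
    """Environment-only capture back-projected to a camera-frame cloud."""
    rng = rng if rng is not None else np.random.default_rng(0)
    depth, _ = render_depth(scene, cam_index, K, include_animal=False)
    depth = _degrade(depth, depth_sigma, 0.0, rng)
    return backproject(depth, K)


def perturb_and_degrade(
    scene: SceneTruth,
    rot_max_deg: float,
    trans_max: float,
    depth_sigma: float,
    dropout: float = 0.0,
    seed: int = 0,
    K: CameraIntrinsics | None = None,
    segmentation: str = "labels",
    seg_cfg: SegmentationConfig = SegmentationConfig(),
) -> CameraRig:
    """Camera rig with noisy clouds and perturbed initial pose estimates.

    Initial poses compose each true pose with an exact rigid delta whose
    rotation angles (per axis, radians) and translation components are
    drawn uniformly within the given bounds — mirroring the bounded
    search box of the comparison protocol.  Depth gets per-pixel Gaussian
    noise and optional validity dropout.  Deterministic given the seed.
    """
    if rot_max_deg < 0 or trans_max < 0 or depth_sigma < 0 or dropout < 0:
        raise ValueError("perturbation magnitudes must be >= 0")
    K = K or scene.config.intrinsics()
    rng = np.random.default_rng(seed)
    cameras = []
    for i, T_true in enumerate(scene.poses):
        theta = np.radians(rng.uniform(-rot_max_deg, rot_max_deg, 3))
        t = rng.uniform(-trans_max, trans_max, 3)
        delta = RigidTransform.from_rotation_translation(
            Rotation.from_euler("xyz", theta).as_matrix(), t
        )
        T_init = delta @ T_true
        cloud = build_camera(
            scene, i, K, depth_sigma=depth_sigma, dropout=dropout, rng=rng,
            segmentation=segmentation, seg_cfg=seg_cfg,
        )
        cameras.append(
            Camera(
                cam_id=i,
                T_init=T_init,
                points=cloud.vertices,
                normals=cloud.vertex_normals,
                T_true=T_true,
            )
        )
    return CameraRig(cameras)
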