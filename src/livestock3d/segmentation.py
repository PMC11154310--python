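"""Isolating the animal surface from a single camera's mesh.

Farm captures contain the floor, fence bars and depth noise besides the
animal.  Segmentation runs four stages on the per-camera grid mesh:

1. background subtraction — vertices within a removal radius of a
   once-built KD-tree over an animal-free capture of the same camera are
   deleted with their triangles;
2. long-edge filtering — triangles straddling depth discontinuities have
   stretched edges; any triangle with an edge longer than twice the mesh's
   mean (unique-edge) length is removed;
3. boundary erosion — vertices on half-edge boundary loops are deleted
   for a few rounds, peeling away the noisy rim left near occluders;
4. drop connected components much smaller than the largest — isolated
   noise blobs — while keeping all the large bands an occluding fence
   slices the visible surface into.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshes import TriMesh

__all__ = [
    "BackgroundIndex",
    "BoundaryLoop",
    "SegmentationConfig",
    "NoAnimalError",
    "remove_background",
    "remove_long_edges",
    "find_boundary_loops",
    "erode_boundary",
    "keep_large_components",
    "segment_animal",
]


class NoAnimalError(RuntimeError):
    """Raised when segmentation leaves nothing — no animal in view."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables: removal radius (m) around environment points, erosion rounds."""

    background_radius: float = 0.02
    erode_rounds: int = 3
    long_edge_factor: float = 2.0
    # fence occlusion slices the animal into several large components;
    # only components much smaller than the largest are noise
    min_component_frac: float = 0.1

    def __post_init__(self):
        if self.background_radius <= 0:
            raise ValueError("background radius must be positive")
        if self.erode_rounds < 0:
            raise ValueError("erosion rounds must be >= 0")


class BackgroundIndex:
    """KD-tree over one camera's environment-only capture, built once."""

    def __init__(self, environment_points: np.ndarray, radius: float = 0.02):
        pts = np.asarray(environment_points, dtype=float).reshape(-1, 3)
        if radius <= 0:
            raise ValueError("removal radius must be positive")
        self.radius = float(radius)
        self.tree = cKDTree(pts) if len(pts) else None

    def near_environment(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points within the removal radius of the environment."""
        points = np.atleast_2d(points)
        if self.tree is None or len(points) == 0:
            return np.zeros(len(points), dtype=bool)
        d, _ = self.tree.query(points, k=1, distance_upper_bound=self.radius)
        return np.isfinite(d)


@dataclass(frozen=True)
class BoundaryLoop:
    """Closed cycle of vertex indices; consecutive pairs are half-edges."""

    vertices: tuple

    def __len__(self):
        return len(self.vertices)


def remove_background(mesh: TriMesh, bg: BackgroundIndex) -> TriMesh:
    """Delete vertices near the environment capture, with incident triangles."""
    if mesh.is_empty():
        return mesh
    near = bg.near_environment(mesh.vertices)
    return mesh.remove_vertices(near)


def remove_long_edges(mesh: TriMesh, factor: float = 2.0) -> TriMesh:
    """Drop triangles containing an edge longer than ``factor`` x mean edge.

    The mean is taken over the unique undirected edges of the *input* mesh,
    computed once (not re-estimated while deleting).
    """
    if mesh.is_empty():
        return mesh
    edges = mesh.unique_edges()
    mean_len = mesh.edge_lengths(edges).mean()
    cutoff = factor * mean_len
    a, b, c = mesh.triangle_corners()
    tri_edge_max = np.maximum(
        np.linalg.norm(a - b, axis=1),
        np.maximum(np.linalg.norm(b - c, axis=1), np.linalg.norm(c - a, axis=1)),
    )
    return mesh.keep_triangles(tri_edge_max <= cutoff)


def find_boundary_loops(mesh: TriMesh) -> list[BoundaryLoop]:
    """Partition all half-edges into closed boundary loops.

    A half-edge is a directed triangle edge whose undirected edge belongs
    to exactly one triangle.  Loops are walked by repeatedly following an
    outgoing half-edge from the current end vertex; on a manifold mesh the
    walk always closes.  An edge contained in more than two triangles is
    non-manifold and raises.
    """
    if mesh.is_empty():
        return []
    directed = mesh.directed_edges()
    und = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(
        und, axis=0, return_inverse=True, return_counts=True
    )
    if counts.max(initial=0) > 2:
        bad = uniq[np.argmax(counts)]
        raise ValueError(
            f"non-manifold edge {tuple(int(x) for x in bad)} "
            f"shared by {int(counts.max())} triangles"
        )
    half = directed[counts[inverse] == 1]
    if len(half) == 0:
        return []

    # successor table: outgoing half-edges indexed by start vertex
    order = np.argsort(half[:, 0], kind="stable")
    half_sorted = half[order]
    starts = half_sorted[:, 0]
    used = np.zeros(len(half_sorted), dtype=bool)
    first_of = np.searchsorted(starts, np.arange(mesh.n_vertices))
    count_of = np.searchsorted(starts, np.arange(mesh.n_vertices), side="right")

    def take_outgoing(v: int) -> int:
        for k in range(first_of[v], count_of[v]):
            if not used[k]:
                return k
        return -1

    loops: list[BoundaryLoop] = []
    for seed in range(len(half_sorted)):
        if used[seed]:
            continue
        k = seed
        cycle = []
        while True:
            used[k] = True
            a, b = half_sorted[k]
            cycle.append(int(a))
            if b == half_sorted[seed, 0]:
                break
            k = take_outgoing(int(b))
            if k < 0:  # dangling chain: only possible on non-manifold vertices
                break
        loops.append(BoundaryLoop(tuple(cycle)))
    return loops


def erode_boundary(mesh: TriMesh, rounds: int) -> TriMesh:
    """Delete all boundary-loop vertices, ``rounds`` times or until closed."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    for _ in range(rounds):
        if mesh.is_empty():
            break
        edges, counts = mesh.unique_edges(return_counts=True)
        boundary_edges = edges[counts == 1]
        if len(boundary_edges) == 0:
            break
        on_boundary = np.zeros(mesh.n_vertices, dtype=bool)
        on_boundary[boundary_edges.ravel()] = True
        mesh = mesh.remove_vertices(on_boundary)
    return mesh


def keep_large_components(mesh: TriMesh, min_frac: float = 0.1) -> TriMesh:
    """Drop connected components smaller than ``min_frac`` of the largest.

    An occluder (fence bar) slices the visible surface into several
    *large* pieces that must all survive; isolated noise patches are
    orders of magnitude smaller and are discarded.
    """
    if mesh.is_empty():
        return mesh
    labels = mesh.connected_components()
    ref = np.unique(mesh.triangles)
    counts = np.bincount(labels[ref], minlength=labels.max() + 1)
    keep_labels = np.flatnonzero(counts >= min_frac * counts.max())
    tri_keep = np.isin(labels[mesh.triangles[:, 0]], keep_labels)
    return mesh.keep_triangles(tri_keep)


def segment_animal(
    frame_mesh: TriMesh,
    bg: BackgroundIndex,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> TriMesh:
    """Full per-camera segmentation pipeline; raises if nothing remains."""
    mesh = remove_background(frame_mesh, bg)
    mesh = remove_long_edges(mesh, cfg.long_edge_factor)
    mesh = erode_boundary(mesh, cfg.erode_rounds)
    if not mesh.is_empty():
        mesh = keep_large_components(mesh, cfg.min_component_frac)
    if mesh.is_empty():
        raise NoAnimalError("segmentation removed every vertex: no animal in view")
    if mesh.n_vertices < frame_mesh.n_vertices and mesh.n_triangles == 0:
        raise NoAnimalError("segmentation left no triangles: no animal in view")
    return mesh
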