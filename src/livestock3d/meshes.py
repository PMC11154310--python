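"""Triangle-mesh container and combinatorial helpers.

``TriMesh`` keeps vertices (meters), counter-clockwise triangles and
optional unit vertex normals as plain numpy arrays.  Heavier geometry
(PLY/OBJ I/O) goes through the ``trimesh`` library at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TriMesh", "mesh_stats", "MeshStats"]


@dataclass
class TriMesh:
    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int, CCW
    vertex_normals: np.ndarray | None = None  # (n, 3) unit vectors

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles):
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle index out of range")
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(
                self.vertex_normals, dtype=float
            ).reshape(-1, 3)
            if len(self.vertex_normals) != len(self.vertices):
                raise ValueError("one normal per vertex required")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def is_empty(self) -> bool:
        return self.n_triangles == 0

    def triangle_corners(self):
        """The three (m, 3) corner arrays of every triangle."""
        v, t = self.vertices, self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def triangle_normals(self, normalized: bool = True) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        if normalized:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(normalized=False), axis=1)

    # -- edges --------------------------------------------------------------

    def directed_edges(self) -> np.ndarray:
        """(3m, 2) directed edges (a,b),(b,c),(c,a) of each triangle."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def unique_edges(self, return_counts: bool = False):
        """Unique undirected edges; optionally how many triangles share each."""
        e = np.sort(self.directed_edges(), axis=1)
        if len(e) == 0:
            e = e.reshape(0, 2)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        if return_counts:
            return uniq, counts
        return uniq

    def edge_lengths(self, edges: np.ndarray | None = None) -> np.ndarray:
        if edges is None:
            edges = self.unique_edges()
        d = self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    # -- restriction / cleanup ----------------------------------------------

    def keep_triangles(self, tri_mask: np.ndarray) -> "TriMesh":
        """Keep the masked triangles, drop now-unreferenced vertices, reindex."""
        tris = self.triangles[np.asarray(tri_mask, dtype=bool)]
        if len(tris) == 0:
            return TriMesh(
                np.zeros((0, 3)),
                np.zeros((0, 3), dtype=np.int64),
                np.zeros((0, 3)) if self.vertex_normals is not None else None,
            )
        used = np.unique(tris)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        normals = (
            self.vertex_normals[used] if self.vertex_normals is not None else None
        )
        return TriMesh(self.vertices[used], remap[tris], normals)

    def remove_vertices(self, vert_mask: np.ndarray) -> "TriMesh":
        """Delete masked vertices together with every incident triangle."""
        vert_mask = np.asarray(vert_mask, dtype=bool)
        if len(self.triangles):
            tri_keep = ~vert_mask[self.triangles].any(axis=1)
        else:
            tri_keep = np.zeros(0, dtype=bool)
        return self.keep_triangles(tri_keep)

    def connected_components(self) -> np.ndarray:
        """Per-vertex component label via the triangle adjacency graph."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = self.n_vertices
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        e = self.directed_edges()
        adj = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        return labels

    def largest_component(self) -> "TriMesh":
        labels = self.connected_components()
        if self.is_empty():
            return self
        # rank components by vertex count among triangle-referenced vertices
        ref = np.unique(self.triangles)
        counts = np.bincount(labels[ref])
        keep_label = int(np.argmax(counts))
        tri_keep = labels[self.triangles[:, 0]] == keep_label
        return self.keep_triangles(tri_keep)

    # -- conversion ---------------------------------------------------------

    def to_trimesh(self):
        import trimesh as _tm

        return _tm.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @classmethod
    def from_trimesh(cls, tm) -> "TriMesh":
        return cls(
            np.asarray(tm.vertices, dtype=float),
            np.asarray(tm.faces, dtype=np.int64),
        )


@dataclass(frozen=True)
class MeshStats:
    n_vertices: int
    n_triangles: int
    n_edges: int
    mean_edge: float
    watertight: bool
    euler_characteristic: int


def mesh_stats(mesh: TriMesh) -> MeshStats:
    """Exact counts, mean unique-edge length and the watertight flag.

    Watertight means no half-edges: every undirected edge is shared by
    exactly two triangles.
    """
    if mesh.is_empty():
        return MeshStats(mesh.n_vertices, 0, 0, float("nan"), False, mesh.n_vertices)
    edges, counts = mesh.unique_edges(return_counts=True)
    lengths = mesh.edge_lengths(edges)
    watertight = bool(np.all(counts == 2))
    euler = mesh.n_vertices - len(edges) + mesh.n_triangles
    return MeshStats(
        n_vertices=mesh.n_vertices,
        n_triangles=mesh.n_triangles,
        n_edges=len(edges),
        mean_edge=float(lengths.mean()),
        watertight=watertight,
        euler_characteristic=int(euler),
    )
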