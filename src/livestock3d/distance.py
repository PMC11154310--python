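"""Exact point-to-mesh distance with a KD-tree over triangle centroids.

The registration data term needs, for many query points, the Euclidean
distance to the closest point on *any* triangle of the current global
mesh, together with that triangle's normal (for point-to-plane
residuals).  The query here is exact: a nearest-centroid probe gives an
upper bound, and every triangle whose centroid lies within
``bound + max_circumradius`` is then checked with the exact
closest-point-on-triangle test, which guarantees the true minimizer is
among the candidates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .meshes import TriMesh

__all__ = ["closest_point_on_triangles", "MeshDistanceQuery", "point_mesh_distance"]


def closest_point_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest point to p on triangle (a, b, c), vectorized over rows.

    Region classification after Ericson, "Real-Time Collision Detection";
    handles vertex, edge and face cases.
    """
    p = np.atleast_2d(p)
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    c = np.atleast_2d(c)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    # vertex regions
    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)

    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = d1 / (d1 - d3)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = d2 / (d2 - d6)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    # edge BC
    va = d3 * d6 - d5 * d4
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    assign(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
        b + w_bc[:, None] * (c - b),
    )

    # face interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    face = a + v[:, None] * ab + w[:, None] * ac
    # degenerate (zero-area) triangles: fall back to the closest clipped edge
    bad = ~done & ~np.isfinite(face).all(axis=1)
    if bad.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            cands = np.stack(
                [
                    a + np.nan_to_num(np.clip(v_ab, 0, 1))[:, None] * ab,
                    a + np.nan_to_num(np.clip(w_ac, 0, 1))[:, None] * ac,
                    b + np.nan_to_num(np.clip(w_bc, 0, 1))[:, None] * (c - b),
                ]
            )
        d = np.linalg.norm(cands - p[None], axis=2)
        pick = np.argmin(d, axis=0)
        face = face.copy()
        rows = np.flatnonzero(bad)
        face[rows] = cands[pick[rows], rows]
    assign(np.ones(len(p), dtype=bool), face)
    return out


class MeshDistanceQuery:
    """Reusable exact nearest-point query against a fixed triangle mesh."""

    def __init__(self, mesh: TriMesh):
        if mesh.is_empty():
            raise ValueError("cannot query distances against an empty mesh")
        self.mesh = mesh
        a, b, c = mesh.triangle_corners()
        self._corners = (a, b, c)
        self._centroids = (a + b + c) / 3.0
        # circumradius bound: farthest corner from the centroid, per triangle
        r = np.maximum(
            np.linalg.norm(a - self._centroids, axis=1),
            np.maximum(
                np.linalg.norm(b - self._centroids, axis=1),
                np.linalg.norm(c - self._centroids, axis=1),
            ),
        )
        # triangles are bucketed by size (median, then doubling) with one
        # KD-tree per bucket, so a handful of oversized membrane triangles
        # cannot inflate the candidate radius of the many regular ones
        edges = [float(np.median(r)) + 1e-12]
        while edges[-1] < float(r.max()):
            edges.append(edges[-1] * 2.0)
        self._buckets = []
        lo = -1.0
        for hi in edges:
            idx = np.flatnonzero((r > lo) & (r <= hi))
            if len(idx):
                self._buckets.append(
                    (idx, cKDTree(self._centroids[idx]), float(r[idx].max()))
                )
            lo = hi
        self._tri_normals = mesh.triangle_normals()

    def _exact_to(self, points: np.ndarray, tri_idx: np.ndarray):
        a, b, c = self._corners
        cp = closest_point_on_triangles(
            points, a[tri_idx], b[tri_idx], c[tri_idx]
        )
        d = np.linalg.norm(points - cp, axis=1)
        return d, cp

    def query(self, points: np.ndarray):
        """Exact (distance, closest point, triangle index) for each point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        ub = np.full(n, np.inf)
        best_cp = np.zeros((n, 3))
        best_tri = np.zeros(n, dtype=np.int64)

        # upper bound: exact distance to the nearest-centroid triangle of
        # every bucket
        for idx, tree, _ in self._buckets:
            _, nearest = tree.query(points, k=1)
            d, cp = self._exact_to(points, idx[nearest])
            better = d < ub
            ub[better] = d[better]
            best_cp[better] = cp[better]
            best_tri[better] = idx[nearest[better]]

        # certification: any closer triangle has its centroid within
        # ub + (that bucket's max circumradius)
        for idx, tree, rmax in self._buckets:
            neighborhoods = tree.query_ball_point(points, ub + rmax + 1e-12)
            lengths = np.fromiter(
                (len(nb) for nb in neighborhoods), dtype=np.int64, count=n
            )
            if lengths.sum() == 0:
                continue
            flat = idx[np.concatenate(
                [np.asarray(nb, dtype=np.int64) for nb in neighborhoods]
            )]
            owner = np.repeat(np.arange(n), lengths)
            d, cp = self._exact_to(points[owner], flat)
            order = np.lexsort((d, owner))
            owner_s = owner[order]
            first = np.searchsorted(owner_s, np.arange(n))
            has = lengths > 0
            sel = order[first[has]]
            rows = np.flatnonzero(has)
            better = d[sel] < ub[rows]
            rows, sel = rows[better], sel[better]
            ub[rows] = d[sel]
            best_cp[rows] = cp[sel]
            best_tri[rows] = flat[sel]
        return ub, best_cp, best_tri

    def triangle_normal(self, tri_idx: np.ndarray) -> np.ndarray:
        return self._tri_normals[tri_idx]

    def point_to_plane(self, points: np.ndarray):
        """Signed point-to-plane residual |n . (p - q)| and its pieces.

        Returns (signed residual, euclidean distance, closest point, normal).
        The normal is that of the closest triangle.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d, cp, tri = self.query(points)
        n = self._tri_normals[tri]
        r = np.einsum("ij,ij->i", points - cp, n)
        return r, d, cp, n


def point_mesh_distance(p: np.ndarray, mesh: TriMesh):
    """Distance (meters), closest point and triangle index for one point.

    Exact Euclidean distance to the closest point on any triangle of the
    mesh; equals the exhaustive per-triangle minimum.
    """
    q = MeshDistanceQuery(mesh)
    d, cp, tri = q.query(np.asarray(p, dtype=float).reshape(1, 3))
    return float(d[0]), cp[0], int(tri[0])
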