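"""Triangulated crown surfaces, polyline curves and nearest-point queries.

Sliding semilandmarks need three geometric primitives per specimen: the
nearest point on the crown mesh (surface re-projection), the nearest point on
a named ridge/sulcus polyline (curve re-projection), and local tangent
directions (curve tangent, surface tangent plane).  All queries here are
vectorized; mesh projection prunes candidate triangles with a KD-tree over
triangle centroids before running an exact point-triangle distance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import InvalidInputError


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each query point.

    Parameters
    ----------
    points : (..., 3)
        Query points; broadcast against the leading axes of ``triangles``.
    triangles : (..., 3, 3)
        Triangle vertices (A, B, C) per query.

    Returns
    -------
    (..., 3) array of closest points (Ericson's region test, fully branchless).
    """
    a, b, c = triangles[..., 0, :], triangles[..., 1, :], triangles[..., 2, :]
    p = points
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
        t_ac = d2 / (d2 - d6)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    t_ab = np.nan_to_num(t_ab)[..., None]
    t_ac = np.nan_to_num(t_ac)[..., None]
    t_bc = np.nan_to_num(t_bc)[..., None]
    v = np.nan_to_num(v)[..., None]
    w = np.nan_to_num(w)[..., None]

    out = a + ab * v + ac * w  # face interior (default)
    m_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(m_bc[..., None], b + (c - b) * t_bc, out)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m_ac[..., None], a + ac * t_ac, out)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m_ab[..., None], a + ab * t_ab, out)
    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[..., None], c, out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[..., None], b, out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[..., None], a, out)
    return out


class Polyline:
    """An ordered 3D polyline parameterized by cumulative arc length."""

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise InvalidInputError("a curve needs >= 2 three-dimensional points")
        self.points = pts
        seg = np.diff(pts, axis=0)
        self.seg_len = np.linalg.norm(seg, axis=1)
        if np.any(self.seg_len <= 0):
            # collapse duplicated vertices rather than failing downstream
            keep = np.concatenate([[True], self.seg_len > 0])
            self.points = pts = pts[keep]
            seg = np.diff(pts, axis=0)
            self.seg_len = np.linalg.norm(seg, axis=1)
        self.seg_dir = seg / self.seg_len[:, None]
        self.cum = np.concatenate([[0.0], np.cumsum(self.seg_len)])
        self.total_length = float(self.cum[-1])

    def point_at(self, s) -> np.ndarray:
        """Point at arc-length parameter ``s`` (clamped to the curve)."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.total_length)
        idx = np.clip(np.searchsorted(self.cum, s, side="right") - 1, 0, len(self.seg_len) - 1)
        t = (s - self.cum[idx])
        return self.points[idx] + self.seg_dir[idx] * t[:, None]

    def tangent_at(self, s, delta: float | None = None) -> np.ndarray:
        """Unit tangent by central differences on the arc-length parameter."""
        if delta is None:
            delta = max(self.total_length / 200.0, 1e-9)
        s = np.atleast_1d(np.asarray(s, dtype=float))
        fwd = self.point_at(s + delta)
        bwd = self.point_at(s - delta)
        d = fwd - bwd
        n = np.linalg.norm(d, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return d / n

    def project(self, q: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest point on the polyline for each query.

        Returns (projected points, arc-length parameters, clamped flags);
        ``clamped`` marks queries whose unconstrained foot fell off an end.
        """
        q = np.atleast_2d(np.asarray(q, dtype=float))
        a = self.points[:-1]            # (S, 3)
        d = self.seg_dir                # (S, 3)
        diff = q[:, None, :] - a[None]  # (m, S, 3)
        t_raw = np.einsum("msk,sk->ms", diff, d)
        t = np.clip(t_raw, 0.0, self.seg_len[None, :])
        cand = a[None] + d[None] * t[..., None]
        dist2 = np.sum((q[:, None, :] - cand) ** 2, axis=-1)
        best = np.argmin(dist2, axis=1)
        m = np.arange(q.shape[0])
        proj = cand[m, best]
        s = self.cum[best] + t[m, best]
        clamped = ((best == 0) & (t_raw[m, best] < 0)) | (
            (best == len(self.seg_len) - 1) & (t_raw[m, best] > self.seg_len[best])
        )
        return proj, s, clamped


@dataclass
class SurfaceGeometry:
    """A specimen's triangulated crown surface plus its named curve polylines."""

    vertices: np.ndarray
    faces: np.ndarray
    curves: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidInputError("faces must be (m, 3) vertex-index triples")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise InvalidInputError("face references an invalid vertex index")
        # drop zero-area faces so downstream normals stay finite
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        self.faces = self.faces[areas > 1e-12]
        self._polylines: Dict[str, Polyline] = {
            name: Polyline(pts) for name, pts in self.curves.items()
        }
        self._mesh: trimesh.Trimesh | None = None
        self._centroid_tree: cKDTree | None = None
        self._triangles: np.ndarray | None = None

    # -- lazy caches -------------------------------------------------------
    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._mesh

    def _ensure_tree(self) -> None:
        if self._centroid_tree is None:
            self._triangles = self.vertices[self.faces]
            self._centroid_tree = cKDTree(self._triangles.mean(axis=1))

    def polyline(self, name: str) -> Polyline:
        try:
            return self._polylines[name]
        except KeyError:
            raise InvalidInputError(f"no curve named {name!r}") from None

    # -- queries -----------------------------------------------------------
    def project_to_surface(
        self, points: np.ndarray, k: int = 24
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest point on the mesh for each query point.

        Candidate triangles are the ``k`` whose centroids are nearest the
        query; the exact point-triangle distance then picks the winner.
        Returns (projections, face indices, distances).
        """
        self._ensure_tree()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k, len(self.faces))
        _, idx = self._centroid_tree.query(pts, k=k)
        idx = np.atleast_2d(idx)
        cand_tri = self._triangles[idx]               # (m, k, 3, 3)
        proj = closest_point_on_triangles(pts[:, None, :], cand_tri)
        d2 = np.sum((proj - pts[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        m = np.arange(pts.shape[0])
        return proj[m, best], idx[m, best], np.sqrt(d2[m, best])

    def surface_normals(self, face_indices: np.ndarray) -> np.ndarray:
        """Smooth outward normal per query: mean of the nearest face's
        area-weighted vertex normals."""
        vn = self.mesh.vertex_normals  # area-weighted by trimesh
        n = vn[self.faces[face_indices]].mean(axis=1)
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return n / norms

    def tangent_plane(self, face_indices: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions per query (from the normal)."""
        n = self.surface_normals(face_indices)
        helper = np.zeros_like(n)
        smallest = np.argmin(np.abs(n), axis=1)
        helper[np.arange(len(n)), smallest] = 1.0
        t1 = np.cross(n, helper)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(n, t1)
        t2 /= np.linalg.norm(t2, axis=1, keepdims=True)
        return t1, t2

    def transformed(
        self,
        scale: float = 1.0,
        rotation: np.ndarray | None = None,
        translation: np.ndarray | None = None,
        warp=None,
    ) -> "SurfaceGeometry":
        """Return a copy with ``warp`` (a point map) and/or a similarity
        transform applied to vertices and curves."""

        def apply(pts: np.ndarray) -> np.ndarray:
            out = np.asarray(pts, dtype=float)
            if warp is not None:
                out = warp(out)
            out = out * scale
            if rotation is not None:
                out = out @ rotation
            if translation is not None:
                out = out + translation
            return out

        return SurfaceGeometry(
            vertices=apply(self.vertices),
            faces=self.faces.copy(),
            curves={name: apply(pts) for name, pts in self.curves.items()},
        )
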