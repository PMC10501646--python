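"""Spherical-mesh utilities shared by registration and resampling.

Point location on a triangulated sphere uses central (gnomonic) projection:
a query direction ``q`` lies in spherical triangle ``(v1, v2, v3)`` iff the
ray through ``q`` intersects the planar triangle, and the barycentric
coordinates of that intersection are all non-negative.  Barycentric
interpolation with these weights is exact for linear functions of the
pre-normalization coordinates, which makes composition of rotational warps
exact to floating point.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def normalize_rows(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=-1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    return x / n


def tangent_project(vec: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Project vectors into the tangent plane of unit points ``at``."""
    return vec - np.einsum("...i,...i->...", vec, at)[..., None] * at


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_rad``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


class SphereLocator:
    """Locate query directions in the triangles of a spherical mesh.

    Candidate triangles are gathered from the faces incident to the k
    nearest vertices of each query; the accepted face is the one whose
    gnomonic barycentric coordinates are most interior.  Queries that land
    in no candidate (numerically) fall back to their nearest vertex.
    """

    def __init__(self, sphere_coords: np.ndarray, faces: np.ndarray):
        self.points = np.asarray(sphere_coords, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tree = cKDTree(self.points)
        n = len(self.points)
        # vertex -> incident faces, padded with -1
        counts = np.zeros(n, dtype=np.int64)
        np.add.at(counts, self.faces.ravel(), 1)
        width = int(counts.max())
        vf = np.full((n, width), -1, dtype=np.int64)
        cursor = np.zeros(n, dtype=np.int64)
        for fi, f in enumerate(self.faces):
            for v in f:
                vf[v, cursor[v]] = fi
                cursor[v] += 1
        self.vertex_faces = vf
        # per-face inverse of the vertex-column matrix: gnomonic
        # barycentric weights are then a matrix-vector product
        M = np.swapaxes(self.points[self.faces], -1, -2)  # (m, 3, 3)
        self.inv_M = np.linalg.inv(M)

    def _solve_candidates(self, q: np.ndarray, cand: np.ndarray):
        """Best face and weights among padded candidate faces per query."""
        valid = cand >= 0
        cand_safe = np.where(valid, cand, 0)
        b = np.einsum("qcij,qj->qci", self.inv_M[cand_safe], q)
        ssum = b.sum(axis=-1)
        good = valid & (ssum > 1e-12) & np.isfinite(ssum)
        with np.errstate(all="ignore"):
            b = b / ssum[..., None]
        score = np.where(good, b.min(axis=-1), -np.inf)
        best = score.argmax(axis=1)
        rows = np.arange(len(q))
        return cand_safe[rows, best], b[rows, best], score[rows, best]

    def locate(
        self, queries: np.ndarray, k: int = 3
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(face_index, barycentric_weights)`` for each query.

        Weights sum to 1 and reproduce the query direction exactly after
        normalization whenever the query lies inside the returned face.
        A first pass checks the faces around each query's nearest vertex;
        misses are retried with a wider candidate ring, then fall back to
        their nearest vertex as a one-hot weight.
        """
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        nq = len(q)
        _, nn1 = self.tree.query(q, k=1)
        nn1 = np.asarray(nn1).reshape(nq)
        face_idx, bary, score = self._solve_candidates(q, self.vertex_faces[nn1])
        miss = score < -1e-9
        if miss.any():
            k = min(max(k, 3), len(self.points))
            _, nn = self.tree.query(q[miss], k=k)
            nn = np.atleast_2d(nn)
            cand = self.vertex_faces[nn].reshape(len(nn), -1)
            f2, b2, s2 = self._solve_candidates(q[miss], cand)
            face_idx[miss], bary[miss] = f2, b2
            score[miss] = s2
            bad = np.flatnonzero(miss)[s2 < -1e-6]
            if len(bad):
                nearest = nn1[bad]
                fb_faces = self.vertex_faces[nearest, 0]
                face_idx[bad] = fb_faces
                onehot = (self.faces[fb_faces] == nearest[:, None]).astype(float)
                bary[bad] = onehot
        return face_idx, bary

    def interpolate(
        self, values: np.ndarray, queries: np.ndarray, k: int = 3
    ) -> np.ndarray:
        """Barycentric interpolation of per-vertex ``values`` at queries."""
        face_idx, bary = self.locate(queries, k=k)
        vals = np.asarray(values, dtype=float)
        return np.einsum("ij,ij->i", vals[self.faces[face_idx]], bary)

    def nearest_vertex(self, queries: np.ndarray) -> np.ndarray:
        _, nn = self.tree.query(np.atleast_2d(queries), k=1)
        return np.asarray(nn).ravel()


def face_scalar_gradients(
    sphere_coords: np.ndarray, faces: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Per-face gradient of the piecewise-linear interpolant of ``values``.

    The gradient lies in each face's plane; evaluated at a point it is then
    projected to the local tangent plane by the caller.
    """
    p = sphere_coords[faces]  # (m, 3, 3)
    v = values[faces]  # (m, 3)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    n = np.cross(e1, e2)
    A = np.stack([e1, e2, n], axis=1)  # (m, 3, 3)
    rhs = np.stack(
        [v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], np.zeros(len(faces))], axis=1
    )
    with np.errstate(all="ignore"):
        g = np.linalg.solve(A, rhs[..., None])[..., 0]
    g[~np.isfinite(g).all(axis=1)] = 0.0
    return g


def spherical_face_orientation(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed orientation (triple product) of each spherical triangle."""
    a, b, c = (points[faces[:, i]] for i in range(3))
    return np.einsum("ij,ij->i", a, np.cross(b, c))


def angular_distance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Geodesic angle (radians) between unit vectors, elementwise."""
    d = np.clip(np.einsum("...i,...i->...", u, v), -1.0, 1.0)
    return np.arccos(d)
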