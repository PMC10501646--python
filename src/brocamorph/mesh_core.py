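"""Triangle-mesh data model and geometric primitives for cortical surfaces.

A cortical hemisphere is represented by a :class:`TriangleMesh` that carries
both its anatomical (folded) geometry in millimetres and a spherical
parameterization — one unit vector per vertex — on which surface
registration operates.  Per-vertex quantities (sulcal depth, cortical
thickness, region probabilities) live in :class:`ScalarMap` containers and
integer region labels in :class:`LabelMap` containers, both indexed against
the mesh's vertex order.

Conventions
-----------
* Coordinates are in mm, right-handed world space.
* Faces are counterclockwise when viewed from outside, so face normals
  computed as ``(b - a) x (c - a)`` point outward.
* Vertex areas follow the barycentric rule: each face contributes one third
  of its area to each of its three vertices.  This is exactly conservative
  (vertex areas sum to the total surface area).
* Regional volumes use the prism approximation ``area x thickness`` summed
  over labeled vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh


@dataclass
class TriangleMesh:
    """A closed triangle mesh with a spherical parameterization.

    Parameters
    ----------
    vertex_coords : (n, 3) float array
        Anatomical vertex positions in mm.
    faces : (m, 3) int array
        Vertex index triples, counterclockwise from outside.
    sphere_coords : (n, 3) float array
        Unit vectors giving each vertex's position on the registration
        sphere.
    hemisphere : {"left", "right"}
    space_tag : str
        Free-text identifier of the template/subject space the mesh lives
        in; used to check that warps and maps are applied to the meshes
        they were computed for.
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    sphere_coords: np.ndarray
    hemisphere: str = "left"
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self, require_closed: bool = True) -> None:
        """Check mesh invariants; raise ``ValueError`` on violation."""
        n = self.n_vertices
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= n:
            raise ValueError("face indices out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise ValueError("degenerate face: repeated vertex index")
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("sphere_coords are not unit length")
        if require_closed:
            edges = np.sort(
                self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            _, counts = np.unique(edges, axis=0, return_counts=True)
            if (counts != 2).any():
                raise ValueError("mesh is not a closed 2-manifold")


@dataclass
class ScalarMap:
    """One real value per vertex of a mesh.

    ``name`` is a semantic tag (``sulcal_depth``, ``thickness_mm``,
    ``probability``, ...) used to enforce simple domain invariants.
    """

    values: np.ndarray
    name: str = "other"
    mesh_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.name == "thickness_mm" and (self.values < 0).any():
            raise ValueError("thickness must be non-negative")
        if self.name == "probability" and (
            (self.values < 0).any() or (self.values > 1).any()
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LabelMap:
    """One non-negative integer region label per vertex; 0 = background."""

    values: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)
    mesh_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if (self.values < 0).any():
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.values)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.values)

    def mask(self, label_id: int) -> np.ndarray:
        return self.values == label_id


# ---------------------------------------------------------------------------
# construction helpers


def icosphere(level: int, radius: float = 1.0, hemisphere: str = "left",
              space_tag: str = "") -> TriangleMesh:
    """Icosphere mesh at the given subdivision level.

    Level 0 is the icosahedron (12 vertices); each level quadruples the
    face count.  The spherical parameterization is the (unit) icosphere
    itself, so synthetic meshes are born with an exact parameterization.
    """
    base = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    sphere = np.asarray(base.vertices, dtype=float)
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    return TriangleMesh(
        vertex_coords=radius * sphere,
        faces=np.asarray(base.faces, dtype=np.int64),
        sphere_coords=sphere,
        hemisphere=hemisphere,
        space_tag=space_tag,
    )


# ---------------------------------------------------------------------------
# geometric primitives


def face_areas(mesh: TriangleMesh, coords: np.ndarray | None = None) -> np.ndarray:
    """Areas of all faces (mm^2) from the cross product of edge vectors."""
    p = mesh.vertex_coords if coords is None else coords
    a, b, c = (p[mesh.faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def vertex_areas(mesh: TriangleMesh, coords: np.ndarray | None = None) -> ScalarMap:
    """Barycentric vertex areas: one third of each incident face's area.

    Degenerate (zero-area) faces contribute nothing and trigger a warning.
    """
    fa = face_areas(mesh, coords)
    if (fa == 0).any():
        warnings.warn(
            f"{int((fa == 0).sum())} zero-area faces contribute no area",
            stacklevel=2,
        )
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return ScalarMap(out, name="vertex_area", mesh_tag=mesh.space_tag)


def label_area(mesh: TriangleMesh, labels: LabelMap, label_id: int) -> float:
    """Surface area (mm^2) of the vertices carrying ``label_id``."""
    if label_id not in labels.label_names:
        raise KeyError(f"unknown label id {label_id}")
    va = vertex_areas(mesh).values
    return float(va[labels.mask(label_id)].sum())


def label_volume(
    mesh: TriangleMesh,
    labels: LabelMap,
    label_id: int,
    thickness: ScalarMap,
) -> float:
    """Regional gray-matter volume (mm^3) as ``sum(area_v * thickness_v)``.

    This is the prism (mid-thickness) approximation: each labeled vertex
    contributes its barycentric surface area times the local cortical
    thickness.
    """
    if label_id not in labels.label_names:
        raise KeyError(f"unknown label id {label_id}")
    if len(thickness) != mesh.n_vertices:
        raise ValueError("thickness does not index this mesh")
    if (thickness.values < 0).any():
        raise ValueError("negative thickness")
    va = vertex_areas(mesh).values
    m = labels.mask(label_id)
    return float((va[m] * thickness.values[m]).sum())


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Neighbor table: for each vertex, the sorted array of edge-sharing
    neighbors."""
    A = adjacency_matrix(mesh)
    return [A.indices[A.indptr[i]: A.indptr[i + 1]] for i in range(mesh.n_vertices)]


def adjacency_matrix(mesh: TriangleMesh) -> sp.csr_matrix:
    """Symmetric boolean vertex adjacency as a CSR matrix (1.0 per edge)."""
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(len(rows))
    A = sp.coo_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2).tocsr()
    A.data[:] = 1.0  # duplicate entries collapse to single edges
    return A


def vertex_normals(mesh: TriangleMesh, coords: np.ndarray | None = None) -> np.ndarray:
    """Outward unit vertex normals (area-weighted average of face normals)."""
    p = mesh.vertex_coords if coords is None else coords
    a, b, c = (p[mesh.faces[:, i]] for i in range(3))
    fn = np.cross(b - a, c - a)  # outward, magnitude = 2*area
    out = np.zeros_like(p)
    for i in range(3):
        np.add.at(out, mesh.faces[:, i], fn)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return out / norms


def mean_edge_length(mesh: TriangleMesh, coords: np.ndarray | None = None) -> float:
    p = mesh.vertex_coords if coords is None else coords
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges = np.unique(edges, axis=0)
    return float(np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1).mean())


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1; an (almost) constant input maps to all
    zeros rather than blowing up."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd < 1e-12:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def compute_sulcal_depth(
    mesh: TriangleMesh, n_iter: int = 50, step: float = 0.5
) -> ScalarMap:
    """Sulcal-depth map from iterative umbrella-Laplacian smoothing.

    Each iteration moves every vertex by ``step`` times the offset to its
    neighbors' centroid.  The depth of a vertex is the accumulated
    displacement projected onto its *original* outward normal: vertices in
    sulcal fundi move outward while smoothing (positive depth), gyral
    crowns move inward (negative).  Because the umbrella operator also
    uniformly shrinks a curved surface (by an amount that depends on local
    vertex valence, not on folding), the same iteration is run on a
    radius-matched reference sphere built from the mesh's spherical
    parameterization and its displacement is subtracted step by step; a
    perfect sphere therefore accumulates exactly zero depth.  The map is
    z-scored across vertices so it is comparable between meshes.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if not (0 < step < 1):
        raise ValueError("step must lie in (0, 1)")
    A = adjacency_matrix(mesh)
    deg = np.asarray(A.sum(axis=1)).ravel()[:, None]
    n0 = vertex_normals(mesh)
    center = mesh.vertex_coords.mean(axis=0)
    p = mesh.vertex_coords - center
    r_bar = np.linalg.norm(p, axis=1).mean()
    q = r_bar * mesh.sphere_coords  # valence-bias reference
    nq = vertex_normals(mesh, coords=q)
    p = p.copy()
    q = q.copy()
    depth = np.zeros(mesh.n_vertices)
    for _ in range(n_iter):
        delta_p = step * (A @ p / deg - p)
        delta_q = step * (A @ q / deg - q)
        depth += np.einsum("ij,ij->i", delta_p, n0)
        depth -= np.einsum("ij,ij->i", delta_q, nq)
        p += delta_p
        q += delta_q
    return ScalarMap(zscore(depth), name="sulcal_depth", mesh_tag=mesh.space_tag)


def mirror_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Mirror a hemisphere across the x = 0 plane.

    Face winding is reversed so normals stay outward; the hemisphere tag is
    flipped.
    """
    M = np.diag([-1.0, 1.0, 1.0])
    other = {"left": "right", "right": "left"}.get(mesh.hemisphere, mesh.hemisphere)
    return TriangleMesh(
        vertex_coords=mesh.vertex_coords @ M,
        faces=mesh.faces[:, ::-1].copy(),
        sphere_coords=mesh.sphere_coords @ M,
        hemisphere=other,
        space_tag=mesh.space_tag,
    )
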