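"""Projection of volumetric label images onto surface vertices.

Histological region segmentations arrive as 3D label volumes in the same
world space as the reconstructed surface.  :func:`project_labels` assigns
each vertex the majority non-background label among nearest-voxel samples
taken along the vertex normal within half the local cortical thickness
(ribbon sampling).  :func:`dice` is the round-trip quality metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import LabelMap, ScalarMap, TriangleMesh, vertex_normals

log = logging.getLogger(__name__)


@dataclass
class LabelVolume:
    """A 3D integer label image with a voxel-index -> world-mm affine."""

    array: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.array.ndim != 3 or self.array.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")


def project_labels(
    vol: LabelVolume,
    mesh: TriangleMesh,
    thickness: ScalarMap,
    n_samples: int = 5,
) -> LabelMap:
    """Ribbon-sample a label volume onto mesh vertices.

    For each vertex, ``n_samples`` points are spaced evenly along the
    outward normal within +/- thickness/2; each is looked up in the volume
    by nearest voxel (labels are categorical, so no interpolation).  The
    vertex receives the majority non-background label; ties break to the
    label of the sample closest to the vertex, then to the smallest label
    id.  Samples outside the volume count as background and are tallied in
    a warning.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(thickness) != mesh.n_vertices:
        raise ValueError("thickness does not index this mesh")
    n = mesh.n_vertices
    normals = vertex_normals(mesh)
    if n_samples == 1:
        offsets = np.zeros((1, 1))
    else:
        offsets = np.linspace(-0.5, 0.5, n_samples)[None, :]
    t = thickness.values[:, None] * offsets  # (n, k)
    pts = mesh.vertex_coords[:, None, :] + t[..., None] * normals[:, None, :]

    inv = np.linalg.inv(vol.affine)
    vox = pts.reshape(-1, 3) @ inv[:3, :3].T + inv[:3, 3]
    ijk = np.rint(vox).astype(np.int64)
    shape = np.array(vol.array.shape)
    inside = ((ijk >= 0) & (ijk < shape)).all(axis=1)
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning(
            "%d of %d ribbon samples fall outside the volume (treated as "
            "background)", n_outside, ijk.shape[0],
        )
    ijk_safe = np.clip(ijk, 0, shape - 1)
    samples = np.where(
        inside, vol.array[ijk_safe[:, 0], ijk_safe[:, 1], ijk_safe[:, 2]], 0
    ).reshape(n, -1)

    k = samples.shape[1]
    max_label = int(samples.max(initial=0))
    values = np.zeros(n, dtype=np.int64)
    if max_label > 0:
        counts = np.zeros((n, max_label + 1), dtype=np.int64)
        rows = np.repeat(np.arange(n), k)
        np.add.at(counts, (rows, samples.ravel()), 1)
        counts[:, 0] = 0  # background never wins by majority
        best = counts.max(axis=1)
        has_label = best > 0
        # tie-break: earliest occurrence in order of |offset from vertex|
        order = np.argsort(np.abs(offsets.ravel()), kind="stable")
        first_occ = np.full((n, max_label + 1), k, dtype=np.int64)
        for pos, col in enumerate(order):
            s = samples[:, col]
            rows_all = np.arange(n)
            cur = first_occ[rows_all, s]
            first_occ[rows_all, s] = np.minimum(cur, pos)
        is_cand = counts == best[:, None]
        is_cand[:, 0] = False
        key = np.where(is_cand, first_occ, k + 1)
        # smallest (first_occ, label_id) among candidates
        lab_ids = np.arange(max_label + 1)[None, :]
        composite = key * (max_label + 2) + lab_ids
        composite = np.where(is_cand, composite, np.iinfo(np.int64).max)
        winner = composite.argmin(axis=1)
        values[has_label] = winner[has_label]
    names = dict(vol.label_names)
    present = set(np.unique(values)) - {0}
    for p in present - set(names):
        names[p] = f"label_{p}"
    return LabelMap(values, label_names=names, mesh_tag=mesh.space_tag)


def dice(labels_a: LabelMap, labels_b: LabelMap, label_id: int) -> float:
    """Soerensen-Dice overlap ``2|A&B| / (|A|+|B|)`` over vertex counts.

    Returns 1.0 when both maps are empty for the label.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label maps index different meshes")
    a = labels_a.mask(label_id)
    b = labels_b.mask(label_id)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
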