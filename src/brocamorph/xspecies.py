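"""Cross-species projection, expansion factors, and containment overlap.

One species' probabilistic atlas (or binary region) is carried through the
template-to-template spherical warp onto the other species' cortical
surface.  Regional volumes are then computed there with the target
template's cortical thickness, so the projected volumes are scaled to the
target brain and directly comparable with volumes reported for that
species.  The expansion factor is the ratio of the reference (target
species) mean volume to the projected mean volume.  Containment overlap
measures how much of a functional region's surface area lies inside a
reference region, optionally swept across atlas thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_stats import ProbAtlas, threshold_atlas
from .mesh_core import LabelMap, ScalarMap, TriangleMesh, label_volume, vertex_areas
from .registration import SphericalWarp, resample_labels, resample_scalar


@dataclass
class VolumeReport:
    """Projected vs. reference regional volumes for one region."""

    region: str
    projected_volumes_mm3: np.ndarray
    projected_mean_mm3: float
    projected_sd_mm3: float | None
    reference_mean_mm3: float
    reference_sd_mm3: float | None
    expansion_factor: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": self.region,
                    "projected_mean_mm3": self.projected_mean_mm3,
                    "projected_sd_mm3": self.projected_sd_mm3,
                    "reference_mean_mm3": self.reference_mean_mm3,
                    "reference_sd_mm3": self.reference_sd_mm3,
                    "expansion_factor": self.expansion_factor,
                }
            ]
        )


@dataclass
class OverlapReport:
    """Containment of functional regions by a reference region across
    atlas thresholds."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def at_threshold(self, t: float) -> pd.DataFrame:
        return self.rows[np.isclose(self.rows["threshold"], t)]


def project_atlas_cross_species(
    atlas: ProbAtlas | None,
    labels: LabelMap | None,
    warp: SphericalWarp,
    dst: TriangleMesh,
) -> tuple[ProbAtlas | None, LabelMap | None]:
    """Carry an atlas and/or a binary label map through a species warp.

    Probability maps travel by barycentric interpolation (values stay in
    [0, 1] by convexity); categorical maps by nearest-vertex transfer.
    """
    out_atlas = None
    out_labels = None
    if atlas is not None:
        prob = resample_scalar(atlas.prob, warp, dst)
        out_atlas = ProbAtlas(
            prob=prob,
            n_subjects=atlas.n_subjects,
            label_id=atlas.label_id,
            label_name=atlas.label_name,
        )
    if labels is not None:
        out_labels = resample_labels(labels, warp, dst)
    return out_atlas, out_labels


def projected_volumes(
    subject_labels_on_b: Sequence[LabelMap],
    dst: TriangleMesh,
    thickness_b: ScalarMap,
    label_id: int,
    reference_mean_mm3: float,
    reference_sd_mm3: float | None = None,
    region: str = "",
) -> VolumeReport:
    """Per-subject projected volumes on the target template and the
    resulting expansion factor.

    The SD across subjects uses the n-1 denominator and is reported as
    absent when fewer than two subjects are given.
    """
    vols = np.array(
        [
            label_volume(dst, lm, label_id, thickness_b)
            for lm in subject_labels_on_b
        ]
    )
    mean = float(vols.mean())
    sd = float(vols.std(ddof=1)) if len(vols) >= 2 else None
    return VolumeReport(
        region=region or str(label_id),
        projected_volumes_mm3=vols,
        projected_mean_mm3=mean,
        projected_sd_mm3=sd,
        reference_mean_mm3=reference_mean_mm3,
        reference_sd_mm3=reference_sd_mm3,
        expansion_factor=expansion_factor(reference_mean_mm3, mean),
    )


def expansion_factor(reference_mean_mm3: float, projected_mean_mm3: float) -> float:
    """How many times larger the reference region is than its projected
    homolog: ``reference / projected``."""
    if projected_mean_mm3 <= 0:
        raise ValueError("projected mean volume must be positive")
    return reference_mean_mm3 / projected_mean_mm3


def containment(
    functional: LabelMap,
    reference: LabelMap,
    mesh: TriangleMesh,
    functional_id: int = 1,
    reference_id: int = 1,
    area_weighted: bool = True,
) -> float:
    """Fraction of the functional region contained by the reference region.

    ``area(F & B) / area(F)`` with barycentric vertex areas as weights
    (``area_weighted=False`` switches to raw vertex counts for
    sensitivity analyses).
    """
    if len(functional) != mesh.n_vertices or len(reference) != mesh.n_vertices:
        raise ValueError("label maps do not index this mesh")
    f = functional.mask(functional_id)
    if not f.any():
        raise ValueError("functional region is empty")
    b = reference.mask(reference_id)
    if area_weighted:
        va = vertex_areas(mesh).values
        return float(va[f & b].sum() / va[f].sum())
    return float((f & b).sum() / f.sum())


def threshold_sweep(
    atlas: ProbAtlas,
    functional_regions: dict[str, LabelMap],
    mesh: TriangleMesh,
    thresholds: Sequence[float],
    area_weighted: bool = True,
) -> OverlapReport:
    """Containment of each functional region at each atlas threshold.

    Raising the threshold shrinks the reference region, so containment is
    non-increasing in the threshold for every functional region.
    """
    rows = []
    for t in thresholds:
        ref = threshold_atlas(atlas, t)
        for name, fmap in functional_regions.items():
            fid = next(iter(set(np.unique(fmap.values)) - {0}), 1)
            rows.append(
                {
                    "region": name,
                    "threshold": float(t),
                    "containment": containment(
                        fmap,
                        ref,
                        mesh,
                        functional_id=int(fid),
                        reference_id=atlas.label_id or 1,
                        area_weighted=area_weighted,
                    ),
                }
            )
    return OverlapReport(rows=pd.DataFrame(rows))


def directional_bias(
    mesh: TriangleMesh,
    region_mask: np.ndarray,
    center_mask: np.ndarray,
    direction: np.ndarray,
) -> float:
    """Fraction of a region's area lying on the positive side of an axis.

    The axis is the tangential ``direction`` through the area centroid of
    ``center_mask``; used to check that the part of one species' region
    not covered by the projected homolog sits on the anterior side.
    """
    va = vertex_areas(mesh).values
    if not region_mask.any():
        raise ValueError("empty region")
    c = (va[center_mask][:, None] * mesh.sphere_coords[center_mask]).sum(axis=0)
    c /= np.linalg.norm(c)
    d = np.asarray(direction, dtype=float)
    d = d - (d @ c) * c
    d /= np.linalg.norm(d)
    coord = (mesh.sphere_coords[region_mask] - c) @ d
    w = va[region_mask]
    return float(w[coord > 0].sum() / w.sum())
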