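"""Probabilistic atlas construction and hemispheric asymmetry statistics.

Registered individual label maps are aggregated vertexwise into a
probabilistic atlas (per-vertex population frequency of the region).
Population-level lateralization is quantified by the standard index
``(L - R) / (L + R)`` on regional surface areas and tested with the
Wilcoxon signed-rank test, reported as ``T = min(W+, W-)``.  With nine
paired hemispheres and no ties the two-sided p-value is exact, computed
from the full null distribution of signed-rank sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .mesh_core import LabelMap, ScalarMap, label_area


@dataclass
class ProbAtlas:
    """Per-vertex population frequency of one region on a template mesh."""

    prob: ScalarMap
    n_subjects: int
    label_id: int = 0
    label_name: str = ""

    def __post_init__(self) -> None:
        v = self.prob.values
        if (v < 0).any() or (v > 1).any():
            raise ValueError("atlas frequencies must lie in [0, 1]")


class WilcoxonResult(NamedTuple):
    T: float
    p_two_sided: float
    n_effective: int
    exact: bool


@dataclass
class AsymmetryReport:
    """Per-subject areas and lateralization plus the population test."""

    label_id: int
    label_name: str
    left_areas_mm2: np.ndarray
    right_areas_mm2: np.ndarray
    lateralization_indices: np.ndarray
    wilcoxon: WilcoxonResult
    subject_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids
                or [f"s{i}" for i in range(len(self.left_areas_mm2))],
                "left_area_mm2": self.left_areas_mm2,
                "right_area_mm2": self.right_areas_mm2,
                "lateralization_index": self.lateralization_indices,
            }
        )


def build_prob_atlas(
    registered_labels: Sequence[LabelMap], label_id: int
) -> ProbAtlas:
    """Vertexwise frequency of ``label_id`` across registered subjects."""
    if len(registered_labels) == 0:
        raise ValueError("need at least one label map")
    n_vertices = len(registered_labels[0])
    counts = np.zeros(n_vertices)
    name = ""
    for lm in registered_labels:
        if len(lm) != n_vertices:
            raise ValueError("label maps have mismatched vertex counts")
        counts += lm.mask(label_id)
        name = lm.label_names.get(label_id, name)
    n = len(registered_labels)
    return ProbAtlas(
        prob=ScalarMap(
            counts / n, name="probability", mesh_tag=registered_labels[0].mesh_tag
        ),
        n_subjects=n,
        label_id=label_id,
        label_name=name,
    )


def threshold_atlas(atlas: ProbAtlas, t: float) -> LabelMap:
    """Binary region: vertices where the population frequency is >= t.

    The boundary is inclusive, so ``t = 0`` labels every vertex; with an
    odd subject count the conventional 0.5 level is unattainable by the
    frequencies themselves and the convention is inert.
    """
    if not (0 <= t <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    values = np.where(atlas.prob.values >= t, atlas.label_id or 1, 0)
    lid = atlas.label_id or 1
    return LabelMap(
        values.astype(np.int64),
        label_names={lid: atlas.label_name or f"label_{lid}"},
        mesh_tag=atlas.prob.mesh_tag,
    )


def lateralization_index(area_left: float, area_right: float) -> float:
    """Standard lateralization index ``(L - R) / (L + R)`` in [-1, 1]."""
    if area_left < 0 or area_right < 0:
        raise ValueError("areas must be non-negative")
    total = area_left + area_right
    if total == 0:
        raise ValueError("both areas are zero; index undefined")
    return (area_left - area_right) / total


def signed_rank_null_counts(n: int) -> np.ndarray:
    """Null distribution of W+ for n untied pairs.

    ``counts[w]`` is the number of the 2^n sign assignments with positive
    rank sum ``w``; computed by the standard polynomial recursion
    (equivalent to full enumeration).
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=np.int64)
    counts[0] = 1
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    left: Sequence[float], right: Sequence[float]
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on left vs. right measurements.

    Zero differences are dropped (Wilcoxon's original rule); absolute
    differences are ranked with midranks.  ``T`` is the smaller of the
    positive and negative rank sums.  With no ties and at most 25
    effective pairs, the two-sided p-value is exact:
    ``p = min(1, 2 * P(W <= T))`` under the symmetric null distribution of
    signed-rank sums.  With ties (where exact enumeration is invalid under
    midranks) or larger n, a normal approximation with continuity and tie
    corrections is used.
    """
    lft = np.asarray(left, dtype=float)
    rgt = np.asarray(right, dtype=float)
    if lft.shape != rgt.shape or lft.ndim != 1 or len(lft) < 2:
        raise ValueError("need equal-length paired samples of length >= 2")
    d = lft - rgt
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    T = min(w_pos, w_neg)
    has_ties = len(np.unique(np.abs(d))) < n
    if not has_ties and n <= 25:
        counts = signed_rank_null_counts(n)
        p = min(1.0, 2.0 * counts[: int(T) + 1].sum() / 2.0**n)
        return WilcoxonResult(T=T, p_two_sided=float(p), n_effective=n, exact=True)
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 -= (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(max(sigma2, 1e-12))
    z = (T - mu + 0.5) / sigma
    p = min(1.0, 2.0 * norm.cdf(z))
    return WilcoxonResult(T=T, p_two_sided=float(p), n_effective=n, exact=False)


def asymmetry_analysis(subjects: Sequence, label_id: int) -> AsymmetryReport:
    """Assemble per-subject L/R areas, lateralization indices, and the
    population Wilcoxon test for one region.

    Each subject must expose ``left`` and ``right`` hemisphere bundles
    with ``mesh`` and ``labels`` attributes (as produced by
    :func:`brocamorph.synthetic.make_population`).
    """
    lefts, rights, lis, ids = [], [], [], []
    name = ""
    for i, s in enumerate(subjects):
        la = label_area(s.left.mesh, s.left.labels, label_id)
        ra = label_area(s.right.mesh, s.right.labels, label_id)
        lefts.append(la)
        rights.append(ra)
        lis.append(lateralization_index(la, ra))
        ids.append(getattr(s, "subject_id", "") or f"s{i}")
        name = s.left.labels.label_names.get(label_id, name)
    res = wilcoxon_signed_rank(lefts, rights)
    return AsymmetryReport(
        label_id=label_id,
        label_name=name,
        left_areas_mm2=np.array(lefts),
        right_areas_mm2=np.array(rights),
        lateralization_indices=np.array(lis),
        wilcoxon=res,
        subject_ids=ids,
    )
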