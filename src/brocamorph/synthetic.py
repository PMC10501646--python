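"""Synthetic two-species cortical populations with known ground truth.

Real cross-species morphometry lacks a ground-truth correspondence between
brains; the generator here provides one by constructing both "species"
templates on the same icosphere parameterization.  A species template is an
icosphere whose radius is perturbed by a sum of smooth von-Mises-like bumps
(a gyrification analog), carrying an analytic sulcal-depth map, a smooth
cortical-thickness field, and geodesic label patches (two cytoarchitectonic
region analogs plus an inferior-frontal-gyrus landmark used for coarse
registration).  Subjects are the template deformed by random smooth
spherical warps with ring-level label jitter; the second species is the
first seen through a known smooth spherical warp, with its first region
expanded anteriorly by a controlled factor.

Everything is deterministic under a fixed seed, and every generated mesh
satisfies the closed-manifold invariants of :mod:`brocamorph.mesh_core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _sphere
from .mesh_core import (
    LabelMap,
    ScalarMap,
    TriangleMesh,
    adjacency_matrix,
    icosphere,
    mirror_mesh,
    vertex_areas,
    zscore,
)
from .registration import SphericalWarp

BA44 = 1
BA45 = 2
LANDMARK = 9
LABEL_NAMES = {BA44: "BA44", BA45: "BA45", LANDMARK: "landmark_IFG"}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class PatchSpec:
    """A geodesic label patch: seed direction plus target area fraction."""

    seed_direction: np.ndarray
    area_fraction: float

    def __post_init__(self) -> None:
        self.seed_direction = _unit(self.seed_direction)
        if not (0 < self.area_fraction < 1):
            raise ValueError("area fraction must lie in (0, 1)")


def _default_patches() -> dict[int, PatchSpec]:
    return {
        BA44: PatchSpec([0.90, 0.35, 0.10], 0.05),
        BA45: PatchSpec([0.55, 0.80, 0.15], 0.04),
    }


@dataclass
class SpeciesSpec:
    """Parameters of one species template.

    The chimpanzee-analog default radius is 40 mm and the human-analog
    55 mm (roughly hemisphere scale); both default to the same thickness
    distribution so cross-species volume ratios are label-driven unless a
    thickness difference is requested explicitly.
    """

    subdiv_level: int = 5
    radius_mm: float = 40.0
    gyri_amplitude_mm: float = 2.5
    n_harmonics: int = 12
    thickness_mean_mm: float = 2.5
    thickness_sd_mm: float = 0.3
    label_patches: dict[int, PatchSpec] = field(default_factory=_default_patches)
    landmark_patch: PatchSpec = field(
        default_factory=lambda: PatchSpec([0.85, 0.50, 0.12], 0.12)
    )
    kappa_range: tuple[float, float] = (8.0, 40.0)
    seed: int = 0
    space_tag: str = "speciesA"

    def __post_init__(self) -> None:
        if self.subdiv_level < 3:
            raise ValueError("subdiv_level must be >= 3")
        total = sum(p.area_fraction for p in self.label_patches.values())
        total += self.landmark_patch.area_fraction
        if total >= 1:
            raise ValueError("patch area fractions must sum to < 1")


@dataclass
class PopulationSpec:
    """Parameters of a synthetic subject population.

    ``n_subjects`` defaults to 9, the size of the retained chimpanzee
    sample.  ``warp_amplitude`` is the maximum tangential displacement (in
    radians) of the random smooth per-subject deformation;
    ``label_jitter`` is the half-width of the uniform integer ring
    erosion/dilation applied to each region, a stand-in for histological
    delineation variability.  ``left_area_inflation`` multiplies the
    left-hemisphere target area of every region, injecting a known
    asymmetry (1.0 = symmetric null).
    """

    n_subjects: int = 9
    warp_amplitude: float = 0.05
    label_jitter: int = 1
    left_area_inflation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.warp_amplitude < 0 or self.label_jitter < 0:
            raise ValueError("warp_amplitude and label_jitter must be >= 0")


@dataclass
class TemplateBundle:
    """A species template: mesh plus its per-vertex fields."""

    mesh: TriangleMesh
    thickness: ScalarMap
    sulcal_depth: ScalarMap
    labels: LabelMap
    radial_bump: np.ndarray  # r(v) - radius, kept for resampling
    spec: SpeciesSpec


@dataclass
class HemiBundle:
    mesh: TriangleMesh
    labels: LabelMap
    thickness: ScalarMap
    sulcal_depth: ScalarMap


@dataclass
class Subject:
    left: HemiBundle
    right: HemiBundle
    subject_id: str = ""


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    true_warps: list[dict[str, SphericalWarp]] = field(default_factory=list)
    species_warp: SphericalWarp | None = None
    true_expansion_factor: dict[int, float] = field(default_factory=dict)
    anterior_shift_direction: np.ndarray | None = None


# ---------------------------------------------------------------------------
# smooth random fields on the sphere


def _bump_field(
    points: np.ndarray,
    rng: np.random.Generator,
    n_components: int,
    kappa_range: tuple[float, float],
) -> np.ndarray:
    """Sum of von-Mises-like bumps ``sum_k s_k exp(kappa_k (u . d_k - 1))``
    with random centers, concentrations, and signs; unit-scale output."""
    dirs = _sphere.normalize_rows(rng.normal(size=(n_components, 3)))
    kappas = rng.uniform(*kappa_range, size=n_components)
    signs = rng.choice([-1.0, 1.0], size=n_components)
    mags = rng.uniform(0.5, 1.0, size=n_components)
    dots = points @ dirs.T  # (n, K)
    return (signs * mags * np.exp(kappas * (dots - 1.0))).sum(axis=1)


def _tangential_warp_field(
    points: np.ndarray,
    rng: np.random.Generator,
    amplitude: float,
    n_components: int = 6,
    kappa_range: tuple[float, float] = (4.0, 12.0),
) -> np.ndarray:
    """Random smooth tangential displacement field, max norm = amplitude."""
    u = np.zeros_like(points)
    centers = _sphere.normalize_rows(rng.normal(size=(n_components, 3)))
    kappas = rng.uniform(*kappa_range, size=n_components)
    vecs = rng.normal(size=(n_components, 3))
    for c, k, v in zip(centers, kappas, vecs):
        g = np.exp(k * (points @ c - 1.0))
        u += g[:, None] * v
    u = _sphere.tangent_project(u, points)
    peak = np.linalg.norm(u, axis=1).max()
    if peak > 0 and amplitude > 0:
        u *= amplitude / peak
    elif amplitude == 0:
        u[:] = 0.0
    return u


def _warp_points(points: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    return _sphere.normalize_rows(points + displacement)


# ---------------------------------------------------------------------------
# patch painting


def _patch_metric(
    points: np.ndarray,
    seed_dir: np.ndarray,
    elongation_dir: np.ndarray | None = None,
    elongation: float = 1.0,
) -> np.ndarray:
    """Anisotropic geodesic distance to a seed direction.

    With ``elongation > 1`` the distance is shrunk along
    ``elongation_dir`` (a tangent at the seed), so sorted-distance growth
    produces patches stretched along that axis.
    """
    s = _unit(seed_dir)
    theta = _sphere.angular_distance(points, s)
    if elongation_dir is None or elongation == 1.0:
        return theta
    t_hat = _unit(_sphere.tangent_project(np.asarray(elongation_dir, float), s))
    n_hat = np.cross(s, t_hat)
    w = points - (points @ s)[:, None] * s
    x = w @ t_hat
    y = w @ n_hat
    phi = np.arctan2(y, x)
    scale = np.sqrt((np.cos(phi) / elongation) ** 2 + np.sin(phi) ** 2)
    return theta * scale


def grow_patch(
    mesh: TriangleMesh,
    seed_direction: np.ndarray,
    area_fraction: float,
    elongation_dir: np.ndarray | None = None,
    elongation: float = 1.0,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of a geodesic patch of the requested area fraction.

    Vertices are accumulated in order of (anisotropic) angular distance to
    the seed until the cumulative vertex area reaches the target fraction
    of the total surface area.  ``exclude`` marks vertices unavailable for
    growth.
    """
    va = vertex_areas(mesh).values
    total = va.sum()
    target = area_fraction * total
    d = _patch_metric(mesh.sphere_coords, seed_direction, elongation_dir, elongation)
    order = np.argsort(d, kind="stable")
    if exclude is not None:
        order = order[~exclude[order]]
    csum = np.cumsum(va[order])
    n_take = int(np.searchsorted(csum, target) + 1)
    if n_take > len(order):
        raise ValueError("patch growth exhausted the mesh")
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[order[:n_take]] = True
    return mask


def _dilate(mask: np.ndarray, A, steps: int, blocked: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for _ in range(steps):
        grown = (A @ out.astype(float)) > 0
        out = out | (grown & ~blocked)
    return out


def _erode(mask: np.ndarray, A, steps: int) -> np.ndarray:
    out = mask.copy()
    for _ in range(steps):
        outside = ~out
        boundary = out & ((A @ outside.astype(float)) > 0)
        out = out & ~boundary
    return out


def adjust_patch_area(
    mesh: TriangleMesh,
    mask: np.ndarray,
    target_area: float,
    blocked: np.ndarray | None = None,
    va: np.ndarray | None = None,
) -> np.ndarray:
    """Grow or shrink a patch, boundary-first, toward a target area (mm^2).

    Candidate vertices are added (removed) in order of distance to the
    patch's spherical centroid, giving near-vertex-level control of the
    final area.  ``blocked`` vertices are never added.
    """
    if va is None:
        va = vertex_areas(mesh).values
    if blocked is None:
        blocked = np.zeros(mesh.n_vertices, dtype=bool)
    A = adjacency_matrix(mesh)
    out = mask.copy()
    if not out.any():
        raise ValueError("cannot adjust an empty patch")
    c = _unit((va[out][:, None] * mesh.sphere_coords[out]).sum(axis=0))
    d = _sphere.angular_distance(mesh.sphere_coords, c)
    for _ in range(10 * mesh.n_vertices):
        area = va[out].sum()
        if area < target_area:
            ring = ((A @ out.astype(float)) > 0) & ~out & ~blocked
            if not ring.any():
                break
            cand = np.flatnonzero(ring)
            cand = cand[np.argsort(d[cand], kind="stable")]
            csum = np.cumsum(va[cand])
            n_take = int(np.searchsorted(csum, target_area - area) + 1)
            out[cand[:n_take]] = True
            if n_take < len(cand):
                break
        elif area > target_area:
            boundary = out & ((A @ (~out).astype(float)) > 0)
            if not boundary.any() or boundary.all():
                break
            cand = np.flatnonzero(boundary)
            cand = cand[np.argsort(-d[cand], kind="stable")]
            csum = np.cumsum(va[cand])
            n_drop = int(np.searchsorted(csum, area - target_area))
            if n_drop == 0:
                break
            out[cand[:n_drop]] = False
            if n_drop < len(cand):
                break
        else:
            break
    return out


# ---------------------------------------------------------------------------
# template and population generation


def _paint_labels(mesh: TriangleMesh, spec: SpeciesSpec) -> LabelMap:
    """Paint region patches in ascending label order, then the landmark;
    each patch grows around the previous ones (exclusion) so every region
    reaches its target area fraction and patches never overlap."""
    values = np.zeros(mesh.n_vertices, dtype=np.int64)
    taken = np.zeros(mesh.n_vertices, dtype=bool)
    for label_id in sorted(spec.label_patches):
        p = spec.label_patches[label_id]
        m = grow_patch(mesh, p.seed_direction, p.area_fraction, exclude=taken)
        values[m] = label_id
        taken |= m
    lm = grow_patch(
        mesh,
        spec.landmark_patch.seed_direction,
        spec.landmark_patch.area_fraction,
        exclude=taken,
    )
    values[lm] = LANDMARK
    return LabelMap(values, label_names=dict(LABEL_NAMES), mesh_tag=mesh.space_tag)


def make_template(spec: SpeciesSpec) -> TemplateBundle:
    """Build one species template from its spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    base = icosphere(spec.subdiv_level, radius=1.0, space_tag=spec.space_tag)
    u = base.sphere_coords
    bump = (
        spec.gyri_amplitude_mm
        * _bump_field(u, rng, spec.n_harmonics, spec.kappa_range)
        if spec.gyri_amplitude_mm > 0
        else np.zeros(len(u))
    )
    mesh = TriangleMesh(
        vertex_coords=(spec.radius_mm + bump)[:, None] * u,
        faces=base.faces,
        sphere_coords=u,
        hemisphere="left",
        space_tag=spec.space_tag,
    )
    depth = ScalarMap(zscore(-bump), name="sulcal_depth", mesh_tag=spec.space_tag)
    t_raw = _bump_field(u, rng, 8, (2.0, 8.0))
    thickness = np.clip(
        spec.thickness_mean_mm + spec.thickness_sd_mm * zscore(t_raw), 0.5, None
    )
    labels = _paint_labels(mesh, spec)
    return TemplateBundle(
        mesh=mesh,
        thickness=ScalarMap(thickness, name="thickness_mm", mesh_tag=spec.space_tag),
        sulcal_depth=depth,
        labels=labels,
        radial_bump=bump,
        spec=spec,
    )


def _mirror_bundle(b: HemiBundle) -> HemiBundle:
    m = mirror_mesh(b.mesh)
    return HemiBundle(
        mesh=m,
        labels=LabelMap(b.labels.values.copy(), dict(b.labels.label_names), m.space_tag),
        thickness=ScalarMap(b.thickness.values.copy(), "thickness_mm", m.space_tag),
        sulcal_depth=ScalarMap(b.sulcal_depth.values.copy(), "sulcal_depth", m.space_tag),
    )


def _jitter_labels(
    mesh: TriangleMesh,
    labels: LabelMap,
    rng: np.random.Generator,
    jitter: int,
    area_scale: dict[int, float] | None = None,
    va: np.ndarray | None = None,
) -> LabelMap:
    """Per-region ring erosion/dilation (uniform in ``{-j..+j}``) plus an
    optional continuous area rescaling.  The landmark patch is never
    jittered itself, and — since the landmark is an IFG analog that
    anatomically contains the regions — region dilation may claim landmark
    vertices but never vertices of another region."""
    if va is None:
        va = vertex_areas(mesh).values
    A = adjacency_matrix(mesh)
    values = labels.values.copy()
    region_ids = [i for i in sorted(labels.label_names) if i != LANDMARK]
    for label_id in region_ids:
        mask = values == label_id
        if not mask.any():
            continue
        blocked = (values != 0) & (values != LANDMARK) & ~mask
        scale = 1.0 if area_scale is None else area_scale.get(label_id, 1.0)
        if scale != 1.0:
            mask = adjust_patch_area(
                mesh, mask, scale * va[mask].sum(), blocked=blocked, va=va
            )
        if jitter > 0:
            k = int(rng.integers(-jitter, jitter + 1))
            if k > 0:
                mask = _dilate(mask, A, k, blocked)
            elif k < 0:
                mask = _erode(mask, A, -k)
        values[values == label_id] = 0
        values[mask] = label_id
    return LabelMap(values, dict(labels.label_names), labels.mesh_tag)


def make_population(
    template: TemplateBundle, pspec: PopulationSpec
) -> tuple[list[Subject], GroundTruth]:
    """Deform the template into a population of two-hemisphere subjects.

    Each subject's left hemisphere is the template composed with a random
    smooth spherical warp: vertex ``i`` of the subject corresponds to
    template sphere location ``phi(s_i)``, from which its radius, depth,
    thickness, and labels are resampled.  The right hemisphere is the
    mirrored left with independently jittered labels (hemisphere pairs are
    mirror images; asymmetry enters only through
    ``pspec.left_area_inflation``).  The true subject-to-template warps
    are returned as ground truth.
    """
    rng = np.random.default_rng(pspec.seed)
    mesh_t = template.mesh
    u = mesh_t.sphere_coords
    spec = template.spec
    loc = _sphere.SphereLocator(u, mesh_t.faces)
    orient0 = np.sign(_sphere.spherical_face_orientation(u, mesh_t.faces))

    subjects: list[Subject] = []
    gt = GroundTruth(anterior_shift_direction=None)
    for i in range(pspec.n_subjects):
        disp = _tangential_warp_field(u, rng, pspec.warp_amplitude)
        phi = _warp_points(u, disp)
        orient = np.sign(_sphere.spherical_face_orientation(phi, mesh_t.faces))
        if (orient != orient0).any():
            n_bad = int((orient != orient0).sum())
            raise ValueError(
                f"subject {i}: warp amplitude {pspec.warp_amplitude} flips "
                f"{n_bad} spherical faces; reduce warp_amplitude"
            )
        tag = f"subj{i:02d}"
        if pspec.warp_amplitude > 0:
            face_idx, bary = loc.locate(phi)
            tri = mesh_t.faces[face_idx]
            bump = np.einsum("ij,ij->i", template.radial_bump[tri], bary)
            depth = np.einsum("ij,ij->i", template.sulcal_depth.values[tri], bary)
            thick = np.einsum("ij,ij->i", template.thickness.values[tri], bary)
            lab = template.labels.values[loc.nearest_vertex(phi)]
        else:
            bump = template.radial_bump.copy()
            depth = template.sulcal_depth.values.copy()
            thick = template.thickness.values.copy()
            lab = template.labels.values.copy()
        mesh_s = TriangleMesh(
            vertex_coords=(spec.radius_mm + bump)[:, None] * u,
            faces=mesh_t.faces,
            sphere_coords=u,
            hemisphere="left",
            space_tag=f"{tag}_L",
        )
        left = HemiBundle(
            mesh=mesh_s,
            labels=LabelMap(lab, dict(template.labels.label_names), mesh_s.space_tag),
            thickness=ScalarMap(np.clip(thick, 0.5, None), "thickness_mm", mesh_s.space_tag),
            sulcal_depth=ScalarMap(depth, "sulcal_depth", mesh_s.space_tag),
        )
        right = _mirror_bundle(left)
        right.mesh.space_tag = f"{tag}_R"
        for m_ in (right.labels, right.thickness, right.sulcal_depth):
            m_.mesh_tag = right.mesh.space_tag

        va_left = vertex_areas(left.mesh).values
        infl = pspec.left_area_inflation
        left.labels = _jitter_labels(
            left.mesh,
            left.labels,
            rng,
            pspec.label_jitter,
            area_scale=None if infl == 1.0 else {k: infl for k in spec.label_patches},
            va=va_left,
        )
        right.labels = _jitter_labels(
            right.mesh, right.labels, rng, pspec.label_jitter, va=va_left
        )

        warp_left = SphericalWarp(
            target_points=phi,
            source_sphere=u,
            source_faces=mesh_t.faces,
            source_tag=mesh_s.space_tag,
            target_tag=mesh_t.space_tag,
        )
        M = np.diag([-1.0, 1.0, 1.0])
        warp_right = SphericalWarp(
            target_points=phi @ M,
            source_sphere=right.mesh.sphere_coords,
            source_faces=right.mesh.faces,
            source_tag=right.mesh.space_tag,
            target_tag=f"{mesh_t.space_tag}_mirrored",
        )
        gt.true_warps.append({"left": warp_left, "right": warp_right})
        subjects.append(Subject(left=left, right=right, subject_id=tag))
    return subjects, gt


# ---------------------------------------------------------------------------
# species pair


def make_species_pair(
    spec_a: SpeciesSpec,
    spec_b: SpeciesSpec,
    expansion: float = 1.6,
    shift_deg: float = 20.0,
    seed: int = 0,
    species_warp_amplitude: float = 0.06,
    depth_divergence: float = 0.2,
) -> tuple[TemplateBundle, TemplateBundle, GroundTruth]:
    """Build two species templates related by a known smooth warp.

    Species B's folding pattern is species A's seen through the species
    warp (plus a small independent component controlled by
    ``depth_divergence``, emulating lineage-specific folding).  B's first
    region (the BA44 analog) contains the warped image of A's region as a
    core and is grown to ``expansion`` times its area, preferentially
    toward ``shift_deg`` along a fixed anterior tangent direction; the
    other regions and the landmark transfer unchanged.  The true warp, the
    realized per-label expansion factors, and the anterior direction are
    returned as ground truth.
    """
    if expansion <= 0:
        raise ValueError("expansion must be positive")
    bundle_a = make_template(spec_a)
    rng = np.random.default_rng(seed)
    mesh_a = bundle_a.mesh
    u = mesh_a.sphere_coords

    disp = _tangential_warp_field(u, rng, species_warp_amplitude)
    phi = _warp_points(u, disp)
    orient0 = np.sign(_sphere.spherical_face_orientation(u, mesh_a.faces))
    orient = np.sign(_sphere.spherical_face_orientation(phi, mesh_a.faces))
    if (orient != orient0).any():
        raise ValueError("species warp amplitude flips spherical faces")
    species_warp = SphericalWarp(
        target_points=phi,
        source_sphere=u,
        source_faces=mesh_a.faces,
        source_tag=spec_a.space_tag,
        target_tag=spec_b.space_tag,
    )

    # B fields: pull A's bump field through the warp onto the B icosphere
    base_b = icosphere(spec_b.subdiv_level, radius=1.0, space_tag=spec_b.space_tag)
    ub = base_b.sphere_coords
    warped_loc = _sphere.SphereLocator(phi, mesh_a.faces)
    face_idx, bary = warped_loc.locate(ub)
    tri = mesh_a.faces[face_idx]
    bump_shape = np.einsum("ij,ij->i", bundle_a.radial_bump[tri], bary)
    if spec_a.gyri_amplitude_mm > 0:
        bump_shape = bump_shape / spec_a.gyri_amplitude_mm
    div = (
        depth_divergence
        * _bump_field(ub, rng, spec_b.n_harmonics, spec_b.kappa_range)
        if depth_divergence > 0
        else 0.0
    )
    bump_b = spec_b.gyri_amplitude_mm * (bump_shape + div)
    mesh_b = TriangleMesh(
        vertex_coords=(spec_b.radius_mm + bump_b)[:, None] * ub,
        faces=base_b.faces,
        sphere_coords=ub,
        hemisphere="left",
        space_tag=spec_b.space_tag,
    )
    depth_b = ScalarMap(zscore(-bump_b), "sulcal_depth", spec_b.space_tag)
    t_raw = _bump_field(ub, rng, 8, (2.0, 8.0))
    thickness_b = ScalarMap(
        np.clip(spec_b.thickness_mean_mm + spec_b.thickness_sd_mm * zscore(t_raw), 0.5, None),
        "thickness_mm",
        spec_b.space_tag,
    )

    # B labels: transfer A's labels through the warp, then expand region 1
    nn = warped_loc.nearest_vertex(ub)
    values_b = bundle_a.labels.values[nn].copy()
    va_b = vertex_areas(mesh_b).values
    # area fractions of the true-warp transfer: the baseline against which
    # the built-in expansion is defined (and which a perfect pipeline,
    # projecting A's regions through the true warp, would measure)
    frac_transfer = {
        k: va_b[values_b == k].sum() / va_b.sum()
        for k in bundle_a.labels.label_names
    }

    seed_a = spec_a.label_patches[BA44].seed_direction
    loc_a = _sphere.SphereLocator(u, mesh_a.faces)
    sf, sb = loc_a.locate(seed_a[None, :])
    seed_b = _unit(np.einsum("ijk,ij->k", phi[mesh_a.faces[sf]], sb))
    # anterior direction: fixed tangent at the transferred seed
    anterior = _unit(_sphere.tangent_project(np.array([0.0, 1.0, 0.0]), seed_b))
    shifted_seed = _sphere.rotation_matrix(
        np.cross(seed_b, anterior), np.deg2rad(shift_deg)
    ) @ seed_b

    core = values_b == BA44
    target_area = expansion * va_b[core].sum()
    # the expanded region may claim landmark (IFG) territory, not BA45's
    blocked = (values_b != 0) & (values_b != LANDMARK) & ~core
    if expansion >= 1.0:
        d = _patch_metric(ub, shifted_seed, elongation_dir=anterior, elongation=1.8)
        avail = ~core & ~blocked
        order = np.flatnonzero(avail)[np.argsort(d[avail], kind="stable")]
        csum = np.cumsum(va_b[order])
        need = target_area - va_b[core].sum()
        n_take = int(np.searchsorted(csum, need))
        if n_take >= len(order):
            raise ValueError("expansion incompatible with mesh size")
        mask = core.copy()
        mask[order[:n_take]] = True
    else:
        d = _patch_metric(ub, shifted_seed, elongation_dir=anterior, elongation=1.8)
        idx = np.flatnonzero(core)[np.argsort(d[core], kind="stable")]
        csum = np.cumsum(va_b[idx])
        n_take = int(np.searchsorted(csum, target_area) + 1)
        mask = np.zeros(len(ub), dtype=bool)
        mask[idx[:n_take]] = True
    values_b[values_b == BA44] = 0
    values_b[mask] = BA44
    labels_b = LabelMap(values_b, dict(bundle_a.labels.label_names), spec_b.space_tag)

    frac_b = {
        k: va_b[labels_b.mask(k)].sum() / va_b.sum() for k in labels_b.label_names
    }
    gt = GroundTruth(
        species_warp=species_warp,
        true_expansion_factor={
            k: frac_b[k] / frac_transfer[k]
            for k in frac_transfer
            if frac_transfer[k] > 0
        },
        anterior_shift_direction=anterior,
    )
    bundle_b = TemplateBundle(
        mesh=mesh_b,
        thickness=thickness_b,
        sulcal_depth=depth_b,
        labels=labels_b,
        radial_bump=bump_b,
        spec=spec_b,
    )
    return bundle_a, bundle_b, gt


def chimp_like(**overrides) -> SpeciesSpec:
    """Chimpanzee-analog template spec (smaller hemisphere)."""
    return replace(SpeciesSpec(space_tag="chimpT"), **overrides)


def human_like(**overrides) -> SpeciesSpec:
    """Human-analog template spec (larger hemisphere)."""
    return replace(
        SpeciesSpec(radius_mm=55.0, gyri_amplitude_mm=3.2, space_tag="humanT"),
        **overrides,
    )


# ---------------------------------------------------------------------------
# rasterization (volumetric label images for projection tests)


def rasterize_labels(
    mesh: TriangleMesh,
    labels: LabelMap,
    thickness: ScalarMap,
    voxel_mm: float,
):
    """Rasterize surface labels into a 3D label volume.

    A voxel takes the label of the nearest labeled vertex whose
    half-thickness ribbon reaches it.  Returns a
    :class:`brocamorph.vol2surf.LabelVolume` whose affine maps 0-based
    voxel indices to world mm.
    """
    import warnings as _warnings

    from scipy.spatial import cKDTree as _KDTree

    from .mesh_core import mean_edge_length
    from .vol2surf import LabelVolume

    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be positive")
    if voxel_mm > mean_edge_length(mesh):
        _warnings.warn(
            "voxel size exceeds mean edge length; projection round-trips "
            "will degrade",
            stacklevel=2,
        )
    labeled = labels.values > 0
    margin = float(thickness.values.max(initial=1.0)) / 2 + voxel_mm
    if labeled.any():
        lo = mesh.vertex_coords[labeled].min(axis=0) - margin
        hi = mesh.vertex_coords[labeled].max(axis=0) + margin
    else:
        lo = mesh.vertex_coords.min(axis=0) - margin
        hi = mesh.vertex_coords.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel_mm).astype(int) + 1, 1)
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_mm
    affine[:3, 3] = lo
    array = np.zeros(shape, dtype=np.int32)
    if labeled.any():
        idx = np.indices(shape).reshape(3, -1).T
        centers = idx * voxel_mm + lo
        pts = mesh.vertex_coords[labeled]
        th = thickness.values[labeled]
        lab = labels.values[labeled]
        tree = _KDTree(pts)
        k = min(4, len(pts))
        dist, nn = tree.query(centers, k=k)
        dist = np.atleast_2d(dist.T).T
        nn = np.atleast_2d(nn.T).T
        within = dist <= th[nn] / 2.0
        first = within.argmax(axis=1)
        any_within = within.any(axis=1)
        vox_label = np.where(any_within, lab[nn[np.arange(len(nn)), first]], 0)
        array.ravel()[:] = vox_label
    return LabelVolume(
        array=array, affine=affine, label_names=dict(labels.label_names)
    )
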