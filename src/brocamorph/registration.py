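"""Two-stage spherical surface registration.

Stage one (:func:`coarse_align`) rigidly rotates the source sphere so that
a gross anatomical landmark patch (an inferior-frontal-gyrus analog)
matches the target's.  Stage two (:func:`fine_register`) refines the
correspondence with a nonrigid, multiresolution optimization driven by
sulcal depth: per-control-vertex tangential displacements minimize the
area-weighted squared depth mismatch plus a discrete Laplacian smoothness
penalty, with backtracking line search so the objective never increases on
an accepted step and folding (flipped spherical triangles) is rejected.

Warps are stored as forward maps: one target-sphere unit point per source
vertex.  Inverse correspondences (needed to pull source data onto target
vertices) are recovered by locating target vertices inside warped source
triangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _sphere
from .mesh_core import (
    LabelMap,
    ScalarMap,
    TriangleMesh,
    icosphere,
    vertex_areas,
)


@dataclass
class SphericalWarp:
    """Per-source-vertex correspondence on the unit sphere.

    ``target_points[i]`` is where source vertex ``i`` lands on the target
    sphere.  The source sphere coordinates and faces are carried along so
    the warp can be composed and inverted without the source mesh at hand.
    """

    target_points: np.ndarray
    source_sphere: np.ndarray
    source_faces: np.ndarray
    source_tag: str = ""
    target_tag: str = ""
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.target_points = np.asarray(self.target_points, dtype=float)
        norms = np.linalg.norm(self.target_points, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("warp target points must be unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.target_points)


@dataclass
class RegistrationParams:
    """Free parameters of the nonrigid stage.

    ``lambda_smooth`` balances depth fidelity against warp smoothness;
    ``levels`` are the icosphere subdivision levels of the coarse-to-fine
    control grids.  Each iteration takes a Gauss-Newton step (backtracking
    line search from the full step; ``step_size`` scales the fallback
    gradient direction) and the level stops at ``tol`` relative objective
    decrease or after ``max_iter_per_level`` iterations.
    """

    lambda_smooth: float = 0.1
    levels: tuple[int, ...] = (3, 4, 5)
    step_size: float = 0.1
    max_iter_per_level: int = 100
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be ascending")


def identity_warp(mesh: TriangleMesh, target_tag: str = "") -> SphericalWarp:
    return SphericalWarp(
        target_points=mesh.sphere_coords.copy(),
        source_sphere=mesh.sphere_coords,
        source_faces=mesh.faces,
        source_tag=mesh.space_tag,
        target_tag=target_tag or mesh.space_tag,
    )


# ---------------------------------------------------------------------------
# stage 1: landmark-driven rigid alignment


def _weighted_sphere_centroid(points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    c = (weights[:, None] * points).sum(axis=0)
    n = np.linalg.norm(c)
    if n < 1e-12:
        raise ValueError("degenerate centroid (weights cancel)")
    return c / n


def coarse_align(
    src: TriangleMesh,
    dst: TriangleMesh,
    src_landmark: LabelMap,
    dst_landmark: LabelMap,
    src_depth: ScalarMap | None = None,
    dst_depth: ScalarMap | None = None,
    landmark_id: int = 9,
) -> SphericalWarp:
    """Rigidly rotate the source sphere to align landmark patches.

    The rotation is solved as a weighted orthogonal Procrustes problem on
    matched direction pairs: the area-weighted centroid of the landmark
    patch (weight 2), plus the whole-surface centroids weighted by the
    positive (sulcal) and negative (gyral) parts of the depth map (weight
    1 each), which fix the roll about the landmark axis.  Without depth
    maps the analogous radial-deviation weights of the anatomical surface
    are used.  If no secondary direction is usable (e.g. a featureless
    sphere) the roll is underdetermined: the landmark centroids alone are
    aligned and a warning is emitted.
    """

    def directions(mesh, landmark, depth):
        m = landmark.mask(landmark_id)
        if not m.any():
            raise ValueError("empty landmark patch")
        va = vertex_areas(mesh).values
        lm_c = _weighted_sphere_centroid(mesh.sphere_coords[m], va[m])
        if depth is not None:
            d = np.asarray(depth.values, dtype=float)
        else:
            r = np.linalg.norm(
                mesh.vertex_coords - mesh.vertex_coords.mean(axis=0), axis=1
            )
            sd = r.std()
            d = (r.mean() - r) / sd if sd > 1e-12 else np.zeros_like(r)
        dirs, ok = [lm_c], [True]
        for w in (np.clip(d, 0, None), np.clip(-d, 0, None)):
            c = ((va * w)[:, None] * mesh.sphere_coords).sum(axis=0)
            norm = np.linalg.norm(c)
            usable = norm > 1e-9
            dirs.append(c / norm if usable else np.zeros(3))
            ok.append(usable)
        return dirs, ok

    dirs_a, ok_a = directions(src, src_landmark, src_depth)
    dirs_b, ok_b = directions(dst, dst_landmark, dst_depth)
    usable = [
        i
        for i in range(3)
        if ok_a[i]
        and ok_b[i]
        and (i == 0 or abs(np.dot(dirs_a[i], dirs_a[0])) < 1 - 1e-6)
    ]
    a1, b1 = dirs_a[0], dirs_b[0]
    if len(usable) < 2:
        warnings.warn(
            "no usable secondary direction; roll about the landmark axis "
            "is underdetermined, aligning centroids only",
            stacklevel=2,
        )
        axis = np.cross(a1, b1)
        if np.linalg.norm(axis) < 1e-12:
            if np.dot(a1, b1) > 0:
                R = np.eye(3)
            else:  # antipodal centroids: rotate pi about any perpendicular
                perp = np.cross(a1, [1.0, 0.0, 0.0])
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.cross(a1, [0.0, 1.0, 0.0])
                R = _sphere.rotation_matrix(perp, np.pi)
        else:
            angle = _sphere.angular_distance(a1, b1)
            R = _sphere.rotation_matrix(axis, float(angle))
    else:
        weights = np.array([2.0, 1.0, 1.0])[usable]
        A = np.stack([dirs_a[i] for i in usable])
        B = np.stack([dirs_b[i] for i in usable])
        # weighted Kabsch with proper-rotation sign correction
        H = (weights[:, None] * A).T @ B
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rotated = _sphere.normalize_rows(src.sphere_coords @ R.T)
    return SphericalWarp(
        target_points=rotated,
        source_sphere=src.sphere_coords,
        source_faces=src.faces,
        source_tag=src.space_tag,
        target_tag=dst.space_tag,
        info={"rotation": R},
    )


# ---------------------------------------------------------------------------
# stage 2: sulcal-depth-driven nonrigid refinement


def _control_weights(points: np.ndarray, level: int):
    """Sparse interpolation weights from an icosphere control grid to the
    given sphere points, plus the control grid itself."""
    import scipy.sparse as sp

    ctrl = icosphere(level)
    loc = _sphere.SphereLocator(ctrl.sphere_coords, ctrl.faces)
    face_idx, bary = loc.locate(points)
    rows = np.repeat(np.arange(len(points)), 3)
    cols = ctrl.faces[face_idx].ravel()
    data = bary.ravel()
    W = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(points), ctrl.n_vertices)
    )
    # control-grid graph Laplacian for the smoothness penalty
    from .mesh_core import adjacency_matrix

    A = adjacency_matrix(ctrl)
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A
    edges = np.sort(ctrl.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges = np.unique(edges, axis=0)
    return W, L, edges


def fine_register(
    src_depth: ScalarMap,
    dst_depth: ScalarMap,
    src: TriangleMesh,
    dst: TriangleMesh,
    init: SphericalWarp | None = None,
    params: RegistrationParams | None = None,
) -> SphericalWarp:
    """Nonrigid spherical registration driven by sulcal depth.

    Minimizes, over tangential control-vertex displacements ``delta`` at
    each multiresolution level,

        E = sum_v A(v) (d_src(v) - d_dst(warp(v)))^2
            + lambda * sum_{(u,v) in control edges} ||delta_u - delta_v||^2

    where ``A`` are source vertex areas on the unit sphere and ``d_dst`` is
    the piecewise-linear interpolant of the target depth.  Gradient descent
    with backtracking guarantees a non-increasing objective; steps that
    flip any spherical triangle are rejected and retried with a halved
    step.  The objective trace per level is stored in ``warp.info``.
    """
    params = params or RegistrationParams()
    if init is None:
        init = identity_warp(src, dst.space_tag)
    ds_raw = np.asarray(src_depth.values, dtype=float)
    dd_raw = np.asarray(dst_depth.values, dtype=float)

    # area weights on the source sphere (unit radius -> scale-free energy)
    A_v = vertex_areas(src, coords=src.sphere_coords).values

    dst_loc = _sphere.SphereLocator(dst.sphere_coords, dst.faces)

    from .mesh_core import adjacency_matrix

    def smoother(mesh):
        A = adjacency_matrix(mesh)
        deg = np.asarray(A.sum(axis=1)).ravel()

        def smooth(values, passes):
            v = values
            for _ in range(passes):
                v = 0.5 * v + 0.5 * (A @ v) / deg
            return v

        return smooth

    smooth_src, smooth_dst = smoother(src), smoother(dst)

    orient0 = np.sign(
        _sphere.spherical_face_orientation(src.sphere_coords, src.faces)
    )

    w = init.target_points.copy()
    traces = []
    flagged = False
    top = params.levels[-1]

    # stage 2a: global rotation against the most-smoothed maps (a rigid
    # refinement of the landmark initialization; 3 parameters, Newton
    # steps with backtracking so the objective is non-increasing)
    passes0 = 4 ** (top - params.levels[0]) if len(params.levels) > 1 else 4
    ds0 = smooth_src(ds_raw, passes0)
    dd0 = smooth_dst(dd_raw, passes0)
    grads0 = _sphere.face_scalar_gradients(dst.sphere_coords, dst.faces, dd0)

    def rot_energy(wn):
        face_idx, bary = dst_loc.locate(wn)
        val = np.einsum("ij,ij->i", dd0[dst.faces[face_idx]], bary)
        r = val - ds0
        return float((A_v * r * r).sum()), r, face_idx

    E, r, face_idx = rot_energy(w)
    rot_trace = [E]
    for _ in range(30):
        g_face = _sphere.tangent_project(grads0[face_idx], w)
        cross = np.cross(w, g_face)
        g = (2.0 * A_v * r) @ cross  # (3,) gradient w.r.t. rotation vector
        H = (cross * (2.0 * A_v)[:, None]).T @ cross + 1e-12 * np.eye(3)
        step_vec = np.linalg.solve(H, -g)
        if not np.isfinite(step_vec).all() or np.linalg.norm(step_vec) < 1e-12:
            break
        accepted = False
        s = 1.0
        for _bt in range(20):
            omega = s * step_vec
            R = _sphere.rotation_matrix(omega, np.linalg.norm(omega))
            w_new = _sphere.normalize_rows(w @ R.T)
            E_new, r_new, fi_new = rot_energy(w_new)
            if E_new < E:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
        rel = (E - E_new) / max(E, 1e-30)
        w, E, r, face_idx = w_new, E_new, r_new, fi_new
        rot_trace.append(E)
        if rel < params.tol:
            break
    traces.append(rot_trace)

    for level in params.levels:
        # coarse-to-fine: smooth both depth maps in proportion to the
        # control-grid spacing so flat regions still feel a pull
        passes = 4 ** (top - level) if level < top else 0
        ds = smooth_src(ds_raw, passes)
        dd = smooth_dst(dd_raw, passes)
        grads = _sphere.face_scalar_gradients(dst.sphere_coords, dst.faces, dd)

        def similarity(w):
            face_idx, bary = dst_loc.locate(w)
            val = np.einsum("ij,ij->i", dd[dst.faces[face_idx]], bary)
            r = val - ds
            return float((A_v * r * r).sum()), r, face_idx

        W, L, edges = _control_weights(src.sphere_coords, level)
        W2 = W.copy()
        W2.data = W2.data**2
        deg_ctrl = np.asarray(L.diagonal()).ravel()
        delta = np.zeros((W.shape[1], 3))
        lam = params.lambda_smooth

        def apply(delta):
            u = W @ delta
            u = _sphere.tangent_project(u, w)
            return _sphere.normalize_rows(w + u)

        def energy(delta):
            wn = apply(delta)
            Esim, r, face_idx = similarity(wn)
            d_uv = delta[edges[:, 0]] - delta[edges[:, 1]]
            Ereg = lam * float((d_uv * d_uv).sum())
            return Esim + Ereg, wn, r, face_idx

        E, wn, r, face_idx = energy(delta)
        trace = [E]
        for _ in range(params.max_iter_per_level):
            # gradient of the similarity term w.r.t. per-vertex positions
            g_face = grads[face_idx]
            g_face = _sphere.tangent_project(g_face, wn)
            g_pos = (2.0 * A_v * r)[:, None] * g_face
            g = W.T @ g_pos + 2.0 * lam * (L @ delta)
            gnorm = np.linalg.norm(g)
            if gnorm < 1e-14:
                break
            # Gauss-Newton direction by Jacobi-preconditioned CG on
            # (J^T J + lam L) d = -g; a handful of iterations is enough to
            # propagate the smoothness term globally
            curv = 2.0 * A_v * np.einsum("ij,ij->i", g_face, g_face)
            pre = W2.T @ curv + 2.0 * lam * deg_ctrl
            pre = np.maximum(pre, 1e-3 * pre.max() + 1e-30)[:, None]

            def hessvec(v):
                s_dir = np.einsum("ij,ij->i", g_face, W @ v)
                return (
                    W.T @ ((2.0 * A_v * s_dir)[:, None] * g_face)
                    + 2.0 * lam * (L @ v)
                )

            d = np.zeros_like(g)
            resid = -g
            z = resid / pre
            p = z
            rz = float((resid * z).sum())
            for _cg in range(40):
                Hp = hessvec(p)
                pHp = float((p * Hp).sum())
                if pHp <= 1e-30:
                    break
                alpha = rz / pHp
                d = d + alpha * p
                resid = resid - alpha * Hp
                z = resid / pre
                rz_new = float((resid * z).sum())
                if rz_new < 1e-12 * rz:
                    break
                p = z + (rz_new / rz) * p
                rz = rz_new
            if not np.isfinite(d).all() or np.abs(d).max() == 0:
                d = -params.step_size * g / pre
            accepted = False
            s = 1.0
            for _bt in range(30):
                cand = delta + s * d
                E_new, wn_new, r_new, fi_new = energy(cand)
                warped = apply(cand)
                orient = _sphere.spherical_face_orientation(warped, src.faces)
                folded = (np.sign(orient) != orient0).any()
                if (E_new < E) and not folded:
                    accepted = True
                    break
                s *= 0.5
            if not accepted:
                flagged = True
                break
            rel = (E - E_new) / max(E, 1e-30)
            delta, E, wn, r, face_idx = cand, E_new, wn_new, r_new, fi_new
            trace.append(E)
            if rel < params.tol:
                break
        w = apply(delta)
        traces.append(trace)

    return SphericalWarp(
        target_points=w,
        source_sphere=src.sphere_coords,
        source_faces=src.faces,
        source_tag=src.space_tag,
        target_tag=dst.space_tag,
        info={"objective_traces": traces, "stalled": flagged},
    )


# ---------------------------------------------------------------------------
# resampling and composition


def _inverse_correspondence(warp: SphericalWarp, dst_points: np.ndarray):
    """Locate target-sphere points inside warped source triangles."""
    loc = _sphere.SphereLocator(warp.target_points, warp.source_faces)
    return loc.locate(np.asarray(dst_points, dtype=float))


def resample_scalar(
    scalar: ScalarMap, warp: SphericalWarp, dst: TriangleMesh
) -> ScalarMap:
    """Pull a source-mesh scalar map onto the target mesh through the warp.

    Each target vertex is located inside the warped source triangulation
    and the source values are barycentrically interpolated there.
    """
    if len(scalar) != warp.n_vertices:
        raise ValueError("scalar map does not index the warp's source mesh")
    face_idx, bary = _inverse_correspondence(warp, dst.sphere_coords)
    vals = np.einsum(
        "ij,ij->i", scalar.values[warp.source_faces[face_idx]], bary
    )
    name = scalar.name
    if name == "probability":
        vals = np.clip(vals, 0.0, 1.0)
    return ScalarMap(vals, name=name, mesh_tag=dst.space_tag)


def resample_labels(
    labels: LabelMap, warp: SphericalWarp, dst: TriangleMesh
) -> LabelMap:
    """Categorical transfer: each target vertex takes the label of the
    nearest warped source vertex (deterministic)."""
    if len(labels) != warp.n_vertices:
        raise ValueError("label map does not index the warp's source mesh")
    tree = cKDTree(warp.target_points)
    _, nn = tree.query(dst.sphere_coords, k=1)
    return LabelMap(
        labels.values[nn],
        label_names=dict(labels.label_names),
        mesh_tag=dst.space_tag,
    )


def compose(w1: SphericalWarp, w2: SphericalWarp) -> SphericalWarp:
    """Composite warp: source of ``w1`` -> target of ``w2``.

    ``w2``'s target points are barycentrically interpolated (then
    renormalized) at ``w1``'s target positions on the intermediate sphere.
    Exact for rotational warps thanks to gnomonic barycentric weights.
    """
    if w1.target_tag != w2.source_tag:
        raise ValueError(
            f"cannot compose: {w1.target_tag!r} != {w2.source_tag!r}"
        )
    loc = _sphere.SphereLocator(w2.source_sphere, w2.source_faces)
    face_idx, bary = loc.locate(w1.target_points)
    pts = np.einsum(
        "ijk,ij->ik", w2.target_points[w2.source_faces[face_idx]], bary
    )
    return SphericalWarp(
        target_points=_sphere.normalize_rows(pts),
        source_sphere=w1.source_sphere,
        source_faces=w1.source_faces,
        source_tag=w1.source_tag,
        target_tag=w2.target_tag,
    )
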