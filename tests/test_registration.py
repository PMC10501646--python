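"""Two-stage spherical registration: alignment, refinement, resampling."""

import numpy as np
import pytest

from brocamorph import (
    LabelMap,
    RegistrationParams,
    ScalarMap,
    TriangleMesh,
    coarse_align,
    compose,
    fine_register,
    icosphere,
    identity_warp,
    resample_labels,
    resample_scalar,
)
from brocamorph._sphere import angular_distance, rotation_matrix
from brocamorph.registration import SphericalWarp


def _rotated(mesh: TriangleMesh, R: np.ndarray, tag: str = "rot") -> TriangleMesh:
    return TriangleMesh(
        mesh.vertex_coords @ R.T, mesh.faces, mesh.sphere_coords @ R.T,
        hemisphere=mesh.hemisphere, space_tag=tag,
    )


def _rotation_warp(mesh: TriangleMesh, R: np.ndarray, src_tag="a", dst_tag="b"):
    return SphericalWarp(
        target_points=mesh.sphere_coords @ R.T,
        source_sphere=mesh.sphere_coords,
        source_faces=mesh.faces,
        source_tag=src_tag,
        target_tag=dst_tag,
    )


class TestCoarseAlign:
    def test_identity_on_identical_inputs(self, template4):
        w = coarse_align(
            template4.mesh, template4.mesh, template4.labels, template4.labels,
            template4.sulcal_depth, template4.sulcal_depth,
        )
        assert np.abs(w.target_points - template4.mesh.sphere_coords).max() < 1e-9

    def test_recovers_known_rotation(self, template4):
        R = rotation_matrix([0.3, 1.0, 0.2], np.deg2rad(17))
        dst = _rotated(template4.mesh, R)
        dd = ScalarMap(template4.sulcal_depth.values.copy(), "sulcal_depth", "rot")
        w = coarse_align(
            template4.mesh, dst, template4.labels, template4.labels,
            template4.sulcal_depth, dd,
        )
        err = angular_distance(
            w.target_points, template4.mesh.sphere_coords @ R.T
        )
        assert err.max() < 1e-6

    def test_empty_landmark_raises(self, template4):
        empty = LabelMap(
            np.zeros(template4.mesh.n_vertices, dtype=int), {9: "landmark_IFG"}
        )
        with pytest.raises(ValueError, match="landmark"):
            coarse_align(template4.mesh, template4.mesh, empty, empty)

    def test_featureless_sphere_warns_and_aligns_centroids(self):
        """On a perfect sphere (no depth signal) only the landmark
        centroid constrains the rotation; the roll is underdetermined."""
        mesh = icosphere(3, radius=10.0, space_tag="s")
        n = mesh.n_vertices
        lm_src = np.where(mesh.sphere_coords[:, 2] > 0.9, 9, 0)
        lm_dst = np.where(mesh.sphere_coords[:, 2] < -0.9, 9, 0)
        src_l = LabelMap(lm_src, {9: "landmark_IFG"})
        dst_l = LabelMap(lm_dst, {9: "landmark_IFG"})
        with pytest.warns(UserWarning, match="roll"):
            w = coarse_align(mesh, mesh, src_l, dst_l)
        # landmark centroid must land on the target centroid (opposite pole)
        moved = w.target_points[lm_src == 9].mean(axis=0)
        assert moved[2] < 0


class TestFineRegister:
    def test_identity_fixed_point(self, template4):
        params = RegistrationParams(levels=(2, 3, 4))
        w = fine_register(
            template4.sulcal_depth, template4.sulcal_depth,
            template4.mesh, template4.mesh, params=params,
        )
        disp = angular_distance(w.target_points, template4.mesh.sphere_coords)
        assert disp.mean() < 1e-3

    def test_objective_non_increasing(self, template4):
        R = rotation_matrix([0, 0, 1], np.deg2rad(3))
        dst = _rotated(template4.mesh, R)
        dd = ScalarMap(template4.sulcal_depth.values.copy(), "sulcal_depth", "rot")
        w = fine_register(
            template4.sulcal_depth, dd, template4.mesh, dst,
            params=RegistrationParams(levels=(2, 3), max_iter_per_level=30),
        )
        for trace in w.info["objective_traces"]:
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_huge_smoothness_returns_initialization(self, template4):
        """With the rigid part already optimal, a very large smoothness
        weight suppresses all nonrigid displacement."""
        R = rotation_matrix([0, 1, 0], np.deg2rad(4))
        dst = _rotated(template4.mesh, R)
        dd = ScalarMap(template4.sulcal_depth.values.copy(), "sulcal_depth", "rot")
        init = _rotation_warp(
            template4.mesh, R, template4.mesh.space_tag, "rot"
        )
        w = fine_register(
            template4.sulcal_depth, dd, template4.mesh, dst, init,
            RegistrationParams(lambda_smooth=1e8, levels=(2, 3), max_iter_per_level=20),
        )
        disp = angular_distance(w.target_points, init.target_points)
        assert disp.max() < 5e-3

    def test_equivariance_under_global_rotation(self, template4):
        """Registering rotated copies gives the rotation-conjugated warp."""
        Rd = rotation_matrix([0, 0, 1], np.deg2rad(4))
        dst = _rotated(template4.mesh, Rd)
        dd = ScalarMap(template4.sulcal_depth.values.copy(), "sulcal_depth", "rot")
        params = RegistrationParams(levels=(2, 3), max_iter_per_level=25)
        w1 = fine_register(
            template4.sulcal_depth, dd, template4.mesh, dst, params=params
        )
        Rg = rotation_matrix([1.0, 0.3, -0.2], 0.9)
        src_r = _rotated(template4.mesh, Rg, "src_r")
        dst_r = _rotated(dst, Rg, "dst_r")
        init = SphericalWarp(
            src_r.sphere_coords.copy(), src_r.sphere_coords, src_r.faces,
            "src_r", "dst_r",
        )
        w2 = fine_register(
            template4.sulcal_depth, dd, src_r, dst_r, init, params
        )
        err = angular_distance(w2.target_points, w1.target_points @ Rg.T)
        assert err.mean() < 1e-3


class TestResampling:
    def test_identity_warp_preserves_scalars(self, template4):
        w = identity_warp(template4.mesh)
        res = resample_scalar(template4.sulcal_depth, w, template4.mesh)
        assert np.abs(res.values - template4.sulcal_depth.values).max() < 1e-9

    def test_constant_map_invariant_under_any_warp(self, template4):
        const = ScalarMap(np.full(template4.mesh.n_vertices, 3.7), "other")
        rng = np.random.default_rng(0)
        R = rotation_matrix(rng.normal(size=3), 0.7)
        w = _rotation_warp(template4.mesh, R)
        dst = _rotated(template4.mesh, R)
        res = resample_scalar(const, w, dst)
        assert np.allclose(res.values, 3.7)

    def test_linear_map_under_rotation_matches_analytic(self, template4):
        """f(x) = a.x resampled through a rotation warp equals a.(R^-1 x)."""
        a = np.array([0.4, -1.1, 0.7])
        f = ScalarMap(template4.mesh.sphere_coords @ a, "other")
        R = rotation_matrix([0.5, 0.2, 1.0], 0.4)
        w = _rotation_warp(template4.mesh, R)
        dst = _rotated(template4.mesh, R)
        res = resample_scalar(f, w, dst)
        expected = (dst.sphere_coords @ R) @ a  # R^-1 applied to dst points
        assert np.abs(res.values - expected).max() < 2e-3

    def test_label_transfer_under_rotation(self, template4):
        from brocamorph.vol2surf import dice

        R = rotation_matrix([0.1, 0.9, 0.3], 0.5)
        w = _rotation_warp(template4.mesh, R)
        dst = _rotated(template4.mesh, R)
        res = resample_labels(template4.labels, w, dst)
        # analytic: dst vertex takes the label of R^-1 (dst vertex)
        analytic = LabelMap(
            template4.labels.values.copy(), dict(template4.labels.label_names)
        )
        assert dice(res, analytic, 1) >= 0.95
        assert dice(res, analytic, 2) >= 0.95

    def test_empty_labels_stay_empty(self, template4):
        empty = LabelMap(np.zeros(template4.mesh.n_vertices, dtype=int), {})
        w = identity_warp(template4.mesh)
        res = resample_labels(empty, w, template4.mesh)
        assert (res.values == 0).all()

    def test_identity_label_roundtrip(self, template4):
        w = identity_warp(template4.mesh)
        res = resample_labels(template4.labels, w, template4.mesh)
        assert np.array_equal(res.values, template4.labels.values)


class TestCompose:
    def test_identity_neutral_element(self, template4):
        ident = identity_warp(template4.mesh)
        R = rotation_matrix([1, 2, 0.5], 0.6)
        w = _rotation_warp(
            template4.mesh, R, src_tag=template4.mesh.space_tag, dst_tag="b"
        )
        left = compose(ident, w)
        assert np.abs(left.target_points - w.target_points).max() < 1e-9
        ident_b = SphericalWarp(
            template4.mesh.sphere_coords @ R.T,
            template4.mesh.sphere_coords @ R.T,
            template4.mesh.faces,
            "b", "b",
        )
        right = compose(w, ident_b)
        assert np.abs(right.target_points - w.target_points).max() < 1e-7

    def test_rotations_compose_analytically(self, template4):
        R1 = rotation_matrix([0.2, 1.0, 0.1], 0.5)
        R2 = rotation_matrix([1.0, -0.4, 0.8], 0.9)
        m = template4.mesh
        w1 = _rotation_warp(m, R1, "a", "b")
        mid = _rotated(m, R1, "b")
        w2 = _rotation_warp(mid, R2, "b", "c")
        w = compose(w1, w2)
        expected = m.sphere_coords @ (R2 @ R1).T
        assert np.abs(w.target_points - expected).max() < 1e-6

    def test_tag_mismatch_rejected(self, template4):
        w = identity_warp(template4.mesh, "x")
        w2 = identity_warp(template4.mesh, "y")
        w2.source_tag = "z"
        with pytest.raises(ValueError, match="compose"):
            compose(w, w2)


class TestWarpValidation:
    def test_non_unit_targets_rejected(self, template4):
        with pytest.raises(ValueError, match="unit"):
            SphericalWarp(
                template4.mesh.sphere_coords * 2.0,
                template4.mesh.sphere_coords,
                template4.mesh.faces,
            )

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RegistrationParams(lambda_smooth=-1.0)
        with pytest.raises(ValueError):
            RegistrationParams(levels=(4, 3))
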