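"""Synthetic species/population generator: determinism, ground truth."""

import numpy as np
import pytest

from brocamorph import (
    LabelMap,
    PopulationSpec,
    ScalarMap,
    containment,
    make_population,
    make_species_pair,
    make_template,
    rasterize_labels,
    resample_scalar,
    vertex_areas,
)
from brocamorph.synthetic import (
    BA44,
    BA45,
    LANDMARK,
    PatchSpec,
    SpeciesSpec,
    chimp_like,
    grow_patch,
    human_like,
)


class TestMakeTemplate:
    def test_deterministic_for_fixed_seed(self):
        a = make_template(chimp_like(subdiv_level=3, seed=5))
        b = make_template(chimp_like(subdiv_level=3, seed=5))
        assert np.array_equal(a.mesh.vertex_coords, b.mesh.vertex_coords)
        assert np.array_equal(a.labels.values, b.labels.values)
        assert np.array_equal(a.thickness.values, b.thickness.values)

    def test_distinct_seeds_differ(self):
        a = make_template(chimp_like(subdiv_level=3, seed=5))
        b = make_template(chimp_like(subdiv_level=3, seed=6))
        assert not np.array_equal(a.mesh.vertex_coords, b.mesh.vertex_coords)

    def test_zero_amplitude_gives_flat_depth_but_labels(self):
        spec = chimp_like(subdiv_level=3, gyri_amplitude_mm=0.0, seed=1)
        bundle = make_template(spec)
        assert np.allclose(bundle.sulcal_depth.values, 0.0)
        assert (bundle.labels.values == BA44).any()

    def test_patch_fraction_hits_target(self, template5):
        va = vertex_areas(template5.mesh).values
        for label_id, patch in template5.spec.label_patches.items():
            frac = va[template5.labels.mask(label_id)].sum() / va.sum()
            assert abs(frac - patch.area_fraction) <= 0.02 * patch.area_fraction

    def test_mesh_passes_manifold_invariants(self, template4):
        template4.mesh.validate()
        assert (template4.thickness.values >= 0.5).all()

    def test_depth_is_zscored(self, template4):
        d = template4.sulcal_depth.values
        assert abs(d.mean()) < 1e-9 and np.isclose(d.std(), 1.0)

    def test_grow_patch_exhaustion_raises(self):
        mesh = make_template(chimp_like(subdiv_level=3, seed=0)).mesh
        taken = np.ones(mesh.n_vertices, dtype=bool)
        taken[:3] = False
        with pytest.raises(ValueError, match="exhausted"):
            grow_patch(mesh, [1.0, 0, 0], 0.5, exclude=taken)


class TestMakePopulation:
    def test_zero_warp_zero_jitter_reproduces_template(self, template4):
        pspec = PopulationSpec(
            n_subjects=2, warp_amplitude=0.0, label_jitter=0, seed=3
        )
        subjects, gt = make_population(template4, pspec)
        s = subjects[0]
        assert np.allclose(s.left.mesh.vertex_coords, template4.mesh.vertex_coords)
        assert np.array_equal(s.left.labels.values, template4.labels.values)
        w = gt.true_warps[0]["left"]
        assert np.abs(w.target_points - template4.mesh.sphere_coords).max() < 1e-12

    def test_fixed_seed_reproducible(self, template4):
        pspec = PopulationSpec(n_subjects=2, seed=4)
        s1, _ = make_population(template4, pspec)
        s2, _ = make_population(template4, pspec)
        assert np.array_equal(
            s1[0].left.mesh.vertex_coords, s2[0].left.mesh.vertex_coords
        )
        assert np.array_equal(s1[1].right.labels.values, s2[1].right.labels.values)

    def test_subject_meshes_are_manifold(self, template4):
        subjects, _ = make_population(template4, PopulationSpec(n_subjects=2, seed=5))
        subjects[0].left.mesh.validate()
        subjects[0].right.mesh.validate()
        assert subjects[0].right.mesh.hemisphere == "right"

    def test_excessive_warp_raises_with_diagnostic(self, template4):
        pspec = PopulationSpec(n_subjects=2, warp_amplitude=0.8, seed=6)
        with pytest.raises(ValueError, match="flips"):
            make_population(template4, pspec)

    def test_ground_truth_warp_reproduces_subject_depth(self, template5):
        """Resampling a subject's depth through its true warp must recover
        the template depth up to interpolation error."""
        subjects, gt = make_population(
            template5, PopulationSpec(n_subjects=2, seed=7)
        )
        res = resample_scalar(
            subjects[0].left.sulcal_depth, gt.true_warps[0]["left"], template5.mesh
        )
        assert np.abs(res.values - template5.sulcal_depth.values).max() < 0.1

    def test_left_area_inflation_inflates_left_only(self, template4):
        pspec = PopulationSpec(
            n_subjects=2, warp_amplitude=0.0, label_jitter=0,
            left_area_inflation=1.3, seed=8,
        )
        subjects, _ = make_population(template4, pspec)
        s = subjects[0]
        va = vertex_areas(s.left.mesh).values
        left = va[s.left.labels.mask(BA44)].sum()
        right = va[s.right.labels.mask(BA44)].sum()
        assert left / right == pytest.approx(1.3, rel=0.05)


class TestSpeciesPair:
    def test_expansion_factor_of_built_patches(self):
        _, _, gt = make_species_pair(
            chimp_like(seed=1), human_like(seed=2), expansion=1.6,
            shift_deg=20.0, seed=3,
        )
        assert gt.true_expansion_factor[BA44] == pytest.approx(1.6, rel=0.03)

    def test_congruent_patches_at_unit_expansion(self):
        from brocamorph.registration import resample_labels

        ba, bb, gt = make_species_pair(
            chimp_like(seed=1), human_like(seed=2), expansion=1.0,
            shift_deg=0.0, seed=3,
        )
        proj = resample_labels(ba.labels, gt.species_warp, bb.mesh)
        c = containment(proj, bb.labels, bb.mesh, BA44, BA44)
        assert c >= 0.97

    def test_large_shift_moves_expansion_off_the_source_patch(self):
        from brocamorph.registration import resample_labels
        from brocamorph.xspecies import directional_bias

        ba, bb, gt = make_species_pair(
            chimp_like(seed=1), human_like(seed=2), expansion=1.6,
            shift_deg=60.0, seed=3,
        )
        proj = resample_labels(ba.labels, gt.species_warp, bb.mesh)
        grown = bb.labels.mask(BA44) & ~proj.mask(BA44)
        va = vertex_areas(bb.mesh).values
        overlap = va[grown & proj.mask(BA44)].sum()
        assert overlap == 0.0  # the anterior growth is disjoint from A's patch
        bias = directional_bias(
            bb.mesh, grown, proj.mask(BA44), gt.anterior_shift_direction
        )
        assert bias > 0.9

    def test_invalid_expansion_rejected(self):
        with pytest.raises(ValueError):
            make_species_pair(
                chimp_like(subdiv_level=3), human_like(subdiv_level=3),
                expansion=0.0,
            )

    def test_deterministic(self):
        a = make_species_pair(
            chimp_like(subdiv_level=3, seed=1), human_like(subdiv_level=3, seed=2),
            seed=3,
        )
        b = make_species_pair(
            chimp_like(subdiv_level=3, seed=1), human_like(subdiv_level=3, seed=2),
            seed=3,
        )
        assert np.array_equal(a[1].labels.values, b[1].labels.values)
        assert np.array_equal(
            a[2].species_warp.target_points, b[2].species_warp.target_points
        )


class TestRasterize:
    def test_empty_label_map_gives_zero_volume(self, template4):
        empty = LabelMap(
            np.zeros(template4.mesh.n_vertices, dtype=int), {}, ""
        )
        vol = rasterize_labels(
            template4.mesh, empty, template4.thickness, voxel_mm=1.0
        )
        assert (vol.array == 0).all()

    def test_single_labeled_vertex_labels_enclosing_voxel(self, template4):
        values = np.zeros(template4.mesh.n_vertices, dtype=int)
        values[100] = 1
        labels = LabelMap(values, {1: "dot"})
        vol = rasterize_labels(
            template4.mesh, labels, template4.thickness, voxel_mm=0.8
        )
        p = template4.mesh.vertex_coords[100]
        inv = np.linalg.inv(vol.affine)
        ijk = np.rint(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        assert vol.array[tuple(ijk)] == 1

    def test_coarse_voxel_warns(self, template4):
        with pytest.warns(UserWarning, match="mean edge"):
            rasterize_labels(
                template4.mesh, template4.labels, template4.thickness,
                voxel_mm=10.0,
            )


class TestSpecValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            PatchSpec([1, 0, 0], 1.5)

    def test_patch_budget(self):
        with pytest.raises(ValueError, match="sum"):
            SpeciesSpec(
                label_patches={
                    1: PatchSpec([1, 0, 0], 0.5),
                    2: PatchSpec([0, 1, 0], 0.5),
                }
            )

    def test_minimum_population(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_subjects=1)
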