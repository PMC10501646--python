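"""Shared fixtures.

Expensive objects (full-resolution templates, the end-to-end synthetic
cross-species run) are built once per session and shared by the unit and
acceptance tests that probe different properties of the same computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from brocamorph import PopulationSpec, TriangleMesh, icosphere, make_template
from brocamorph.pipeline import CrossSpeciesResult, run_cross_species_analysis
from brocamorph.synthetic import chimp_like


def make_tetrahedron(edge: float = 1.0) -> TriangleMesh:
    """Regular tetrahedron surface with the requested edge length."""
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    scale = edge / np.linalg.norm(v[0] - v[1])
    faces = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    # orient all faces outward
    for i, f in enumerate(faces):
        a, b, c = v[f]
        if np.dot(a, np.cross(b - a, c - a)) < 0:
            faces[i] = f[::-1]
    return TriangleMesh(
        vertex_coords=scale * v, faces=faces, sphere_coords=v.copy()
    )


@pytest.fixture(scope="session")
def tetrahedron() -> TriangleMesh:
    return make_tetrahedron()


@pytest.fixture(scope="session")
def ico3() -> TriangleMesh:
    return icosphere(3, radius=10.0)


@pytest.fixture(scope="session")
def template4():
    """Chimpanzee-analog template at subdivision 4 (fast unit tests)."""
    return make_template(chimp_like(subdiv_level=4, seed=7))


@pytest.fixture(scope="session")
def template5():
    """Chimpanzee-analog template at the default subdivision 5."""
    return make_template(chimp_like(seed=7))


@pytest.fixture(scope="session")
def e2e() -> CrossSpeciesResult:
    """Full cross-species pipeline on the default synthetic conditions:
    expansion 1.6, anterior shift 20 degrees, nine subjects, default
    registration parameters at subdivision 5."""
    return run_cross_species_analysis(seed=1)


@pytest.fixture(scope="session")
def null_population_template():
    """Template reused across the statistical-calibration simulations."""
    return make_template(chimp_like(seed=11))


def calibration_pspec(seed: int, inflation: float = 1.0) -> PopulationSpec:
    """Population conditions for the symmetry-test calibration: n=9,
    ring-level label jitter, no geometric warp (areas are what the test
    consumes), and an optional left-area inflation."""
    return PopulationSpec(
        n_subjects=9,
        warp_amplitude=0.0,
        label_jitter=1,
        left_area_inflation=inflation,
        seed=seed,
    )
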