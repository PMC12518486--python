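"""Shared fixtures: synthetic templates, populations and fitted models.

Everything is generated programmatically at session scope so the expensive
geometry is built once; fixtures are deterministic (fixed seeds).
"""

import numpy as np
import pytest

from shapecomplete import (ShapeModel, TriangleMesh, build_ssm, default_modes,
                           generate_population, gpa, make_template)


@pytest.fixture(scope="session")
def tetrahedron():
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, faces)


@pytest.fixture(scope="session")
def template_small():
    """A 600-vertex radius template with landmarks and landmark indices."""
    return make_template(600)


@pytest.fixture(scope="session")
def population_small(template_small):
    """12 noise-free shapes over the six built-in modes (seed 2)."""
    template, _, lm_idx = template_small
    modes = default_modes(template)
    return generate_population(template, modes, 12, 0.0, seed=2,
                               landmark_indices=lm_idx)


@pytest.fixture(scope="session")
def model_small(population_small):
    aligned, _ = gpa(population_small.meshes)
    return build_ssm(aligned)


@pytest.fixture(scope="session")
def toy_model():
    """Hand-built 10-vertex, 3-component model for linear-algebra oracles."""
    rng = np.random.default_rng(11)
    n = 10
    verts = rng.normal(size=(n, 3)) * 10.0
    faces = np.array([[0, 1, 2], [2, 3, 4], [4, 5, 6], [6, 7, 8],
                      [8, 9, 0], [1, 3, 5]])
    mean = verts.ravel()
    basis, _ = np.linalg.qr(rng.normal(size=(3 * n, 3)))
    eigenvalues = np.array([25.0, 9.0, 1.0])
    return ShapeModel(TriangleMesh(verts, faces), mean, eigenvalues, basis,
                      {"n_training": 4})


@pytest.fixture(scope="session")
def model_at_scale():
    """An 80-shape model at full working resolution (2000 vertices).

    Session-scoped because the completion self-consistency and specificity
    checks need realistic mesh density.
    """
    template, _, lm_idx = make_template(2000)
    modes = default_modes(template)
    pop = generate_population(template, modes, 80, 0.0, seed=2,
                              landmark_indices=lm_idx)
    aligned, _ = gpa(pop.meshes)
    return build_ssm(aligned)
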