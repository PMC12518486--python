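"""Synthetic radius generator: templates, modes, populations, remeshing."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from shapecomplete import (ShapeMode, TriangleMesh, ValidationError,
                           default_modes, generate_population, make_template,
                           remesh_copy)
from shapecomplete.geometry import surface_distance
from shapecomplete.synthetic import apply_distal_rotation


class TestTemplate:
    def test_dimensions_and_landmarks(self):
        mesh, lms, idx = make_template(800, length_mm=240, shaft_radius_mm=8,
                                       head_radius_mm=11, distal_width_mm=30)
        y = mesh.vertices[:, 1]
        assert y.min() == pytest.approx(0.0, abs=1e-6)
        assert y.max() == pytest.approx(240.0, abs=1e-6)
        assert lms.head_center[1] == pytest.approx(0.0, abs=1e-6)
        assert lms.ridge_midpoint[1] == pytest.approx(240.0, abs=1e-6)
        assert lms.notch_point[2] > 0          # +Z side
        for name, i in idx.items():
            assert np.allclose(mesh.vertices[i], getattr(lms, name))

    def test_closed_manifold_with_positive_volume(self, template_small):
        mesh, _, _ = template_small
        assert mesh.is_closed_manifold()
        assert mesh.signed_volume() > 0

    @pytest.mark.parametrize("kwargs", [
        {"n_vertices": 100},
        {"head_radius_mm": 500.0},
        {"length_mm": -1.0},
    ])
    def test_inconsistent_dimensions_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_template(**{"n_vertices": 800, **kwargs})


class TestModes:
    def test_unit_rms_invariant(self, template_small):
        mesh, _, _ = template_small
        for mode in default_modes(mesh):
            rms = np.sqrt((mode.displacement ** 2).sum(axis=1).mean())
            assert rms == pytest.approx(1.0, abs=1e-12)

    def test_non_unit_field_rejected(self, template_small):
        mesh, _, _ = template_small
        with pytest.raises(ValidationError):
            ShapeMode("bad", np.ones((mesh.n_vertices, 3)), 1.0)

    def test_distal_modes_vanish_proximally(self, template_small):
        mesh, _, _ = template_small
        y = mesh.vertices[:, 1]
        L = y.max() - y.min()
        for mode in default_modes(mesh):
            if mode.name.startswith("distal"):
                prox = y < y.min() + 0.8 * L
                assert np.abs(mode.displacement[prox]).max() == 0.0


class TestPopulation:
    def test_rank_equals_mode_count_without_noise(self, population_small):
        X = np.stack([m.vertices.ravel() for m in population_small.meshes])
        s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        rank = int((s > s[0] * 1e-9).sum())
        assert rank == len(population_small.modes)

    def test_noise_gives_full_generic_rank(self, template_small):
        mesh, _, _ = template_small
        pop = generate_population(mesh, default_modes(mesh), 20, 0.05, seed=4)
        X = np.stack([m.vertices.ravel() for m in pop.meshes])
        s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        assert int((s > s[0] * 1e-9).sum()) == 19        # n - 1

    def test_same_seed_bitwise_identical(self, template_small):
        mesh, _, _ = template_small
        modes = default_modes(mesh)
        a = generate_population(mesh, modes, 5, 0.3, seed=10)
        b = generate_population(mesh, modes, 5, 0.3, seed=10)
        for ma, mb in zip(a.meshes, b.meshes):
            assert (ma.vertices == mb.vertices).all()
        assert (a.latents == b.latents).all()

    def test_seed_is_mandatory(self, template_small):
        mesh, _, _ = template_small
        with pytest.raises(ValidationError, match="seed"):
            generate_population(mesh, default_modes(mesh), 5, 0.0, seed=None)

    def test_pca_recovers_mode_subspace(self, template_small):
        # principal angles between the PCA span of a noise-free population
        # and the true generator modes stay below 1 degree
        mesh, _, _ = template_small
        modes = default_modes(mesh)[:5]
        pop = generate_population(mesh, modes, 60, 0.0, seed=6)
        X = np.stack([m.vertices.ravel() for m in pop.meshes])
        _, _, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        true = np.stack([m.displacement.ravel() for m in modes]).T
        angles = subspace_angles(Vt[:5].T, true)
        assert np.rad2deg(angles).max() < 1.0

    def test_population_mean_converges_to_template(self, template_small):
        mesh, _, _ = template_small
        modes = default_modes(mesh)
        pop = generate_population(mesh, modes, 100, 0.0, seed=8)
        mean = np.mean([m.vertices for m in pop.meshes], axis=0)
        rms = np.sqrt(((mean - mesh.vertices) ** 2).sum(axis=1).mean())
        sd_max = max(m.sd_mm for m in modes)
        assert rms < 3 * sd_max / np.sqrt(pop.n_shapes)

    def test_write_artifacts(self, population_small, tmp_path):
        out = population_small.write(tmp_path / "pop")
        assert len(list(out.glob("shape_*.ply"))) == population_small.n_shapes
        latents = np.loadtxt(out / "latents.csv", delimiter=",", skiprows=1)
        assert latents.shape == population_small.latents.shape


class TestRemeshCopy:
    def test_surface_distance_and_fresh_topology(self, template_small):
        mesh, _, _ = template_small
        copy = remesh_copy(mesh, 500, seed=3)
        d = surface_distance(copy.vertices, mesh)
        assert d.max() < 0.1
        assert copy.n_faces != mesh.n_faces

    def test_seeds_give_different_placements(self, template_small):
        mesh, _, _ = template_small
        a = remesh_copy(mesh, 500, seed=1)
        b = remesh_copy(mesh, 500, seed=2)
        assert a.vertices.shape != b.vertices.shape or \
            not np.allclose(a.vertices, b.vertices)
        for c in (a, b):
            assert surface_distance(c.vertices, mesh).max() < 0.1


class TestDistalRotation:
    def test_distal_vertices_rotate_by_exact_angle(self, template_small):
        mesh, _, _ = template_small
        tilted = apply_distal_rotation(mesh, 5.0, axis="z", fraction=0.88)
        y = mesh.vertices[:, 1]
        lo, hi = y.min(), y.max()
        distal = y > lo + 0.88 * (hi - lo)
        moved = tilted.vertices[distal]
        orig = mesh.vertices[distal]
        pivot = orig.mean(axis=0)
        # exact rigid rotation: recover it by Kabsch and check the angle
        from shapecomplete.geometry import kabsch
        R, _ = kabsch(orig - pivot, moved - pivot)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(5.0, abs=1e-9)
        # proximal region untouched
        prox = y < lo + 0.80 * (hi - lo)
        assert np.abs(tilted.vertices[prox] - mesh.vertices[prox]).max() == 0.0
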