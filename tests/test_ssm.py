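"""Procrustes alignment, PCA model building, sampling/projection, persistence."""

import h5py
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapecomplete import (ModelIntegrityError, ShapeModel, TopologyError,
                           TriangleMesh, ValidationError, build_ssm,
                           default_modes, generate_population, gpa,
                           make_template, two_pass_build)
from shapecomplete.geometry import apply_rigid, kabsch


class TestGPA:
    def test_two_copies_one_displaced(self, template_small):
        mesh, _, _ = template_small
        R = Rotation.from_euler("zx", [6, -4], degrees=True).as_matrix()
        moved = TriangleMesh(apply_rigid(R, np.array([5.0, 2, -3]),
                                         mesh.vertices), mesh.faces)
        aligned, mean = gpa([mesh.copy(), moved])
        mean_pts = mean.reshape(-1, 3)
        for m in aligned:
            assert np.abs(m.vertices - mean_pts).max() < 1e-6

    def test_recovers_mean_under_rigid_perturbations(self, population_small):
        rng = np.random.default_rng(5)
        perturbed = []
        for m in population_small.meshes:
            R = Rotation.from_rotvec(
                np.deg2rad(10) * rng.uniform(-1, 1) * rng.normal(size=3)
                / np.linalg.norm(rng.normal(size=3))).as_matrix()
            t = rng.uniform(-10, 10, size=3)
            perturbed.append(TriangleMesh(apply_rigid(R, t, m.vertices),
                                          m.faces))
        _, mean = gpa(perturbed)
        true_mean = np.mean([m.vertices for m in population_small.meshes],
                            axis=0)
        # compare up to a global rigid motion
        R, t = kabsch(mean.reshape(-1, 3), true_mean)
        aligned_mean = apply_rigid(R, t, mean.reshape(-1, 3))
        rms = np.sqrt(((aligned_mean - true_mean) ** 2).sum(axis=1).mean())
        assert rms < 0.1

    def test_topology_mismatch_rejected(self, template_small, tetrahedron):
        mesh, _, _ = template_small
        with pytest.raises(TopologyError):
            gpa([mesh, tetrahedron])


class TestBuildSSM:
    def test_eighty_generic_shapes_keep_exactly_79_components(self):
        template, _, _ = make_template(300)
        pop = generate_population(template, default_modes(template), 80,
                                  0.3, seed=1)
        aligned, _ = gpa(pop.meshes)
        model = build_ssm(aligned)
        assert model.n_components == 79
        curve = np.cumsum(model.eigenvalues) / model.eigenvalues.sum()
        assert curve[-1] == pytest.approx(1.0, abs=1e-12)

    def test_five_true_modes_give_five_components(self, template_small):
        mesh, _, _ = template_small
        modes = default_modes(mesh)[:5]
        pop = generate_population(mesh, modes, 40, 0.0, seed=3)
        model = build_ssm(pop.meshes)      # corresponded and aligned as built
        assert model.n_components == 5
        curve = np.cumsum(model.eigenvalues) / model.eigenvalues.sum()
        assert curve[4] == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_match_gram_matrix_oracle(self):
        # 3 shapes: nonzero eigenvalues equal those of the 3x3 Gram matrix
        # of centred shape vectors divided by (n - 1)
        rng = np.random.default_rng(8)
        verts = rng.normal(size=(12, 3))
        faces = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]])
        meshes = [TriangleMesh(verts + rng.normal(scale=2.0, size=(12, 3)),
                               faces) for _ in range(3)]
        X = np.stack([m.vertices.ravel() for m in meshes])
        Xc = X - X.mean(axis=0)
        gram_eigs = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / 2))[::-1]
        model = build_ssm(meshes)
        assert model.n_components == 2
        assert np.allclose(model.eigenvalues, gram_eigs[:2], rtol=1e-10)

    def test_mean_equals_average_exactly(self, model_small, population_small):
        aligned, mean = gpa(population_small.meshes)
        model = build_ssm(aligned)
        assert (model.mean == mean).all()


class TestSampleProject:
    def test_zero_coefficients_give_mean(self, model_small):
        sampled = model_small.sample_shape(np.zeros(model_small.n_components))
        assert (sampled.vertices.ravel() == model_small.mean).all()

    def test_project_sample_roundtrip(self, model_small):
        c = np.zeros(model_small.n_components)
        c[0] = 1.0
        rec = model_small.project(model_small.sample_shape(c))
        assert np.abs(rec - c).max() < 1e-9

    def test_project_mean_is_zero(self, model_small):
        assert np.abs(model_small.project(model_small.mean_mesh())).max() < 1e-9

    def test_out_of_subspace_residual_orthogonal(self, model_small):
        rng = np.random.default_rng(2)
        shape = model_small.mean + rng.normal(size=model_small.mean.shape)
        c = model_small.project(shape)
        rec = model_small.reconstruct(c).vertices.ravel()
        residual = shape - rec
        assert np.abs(model_small.basis.T @ residual).max() < 1e-8

    def test_too_many_coefficients_rejected(self, model_small):
        with pytest.raises(ValidationError):
            model_small.sample_shape(np.zeros(model_small.n_components + 1))

    def test_monte_carlo_variance_matches_closed_form(self, toy_model):
        rng = np.random.default_rng(0)
        samples = np.stack([
            toy_model.sample_shape(rng.standard_normal(3)).vertices.ravel()
            for _ in range(10_000)])
        empirical = samples.var(axis=0)
        closed = (toy_model.basis ** 2) @ toy_model.eigenvalues
        assert np.abs(empirical - closed).max() / closed.max() < 0.05


class TestPersistence:
    def test_lossless_roundtrip(self, model_small, tmp_path):
        path = model_small.save(tmp_path / "model.h5")
        back = ShapeModel.load(path)
        assert (back.mean == model_small.mean).all()
        assert (back.eigenvalues == model_small.eigenvalues).all()
        assert (back.basis == model_small.basis).all()
        assert (back.reference.faces == model_small.reference.faces).all()
        assert back.metadata == model_small.metadata

    def test_corrupted_file_fails_checksum(self, model_small, tmp_path):
        path = model_small.save(tmp_path / "model.h5")
        with h5py.File(path, "r+") as f:
            f["mean"][0] = f["mean"][0] + 1.0
        with pytest.raises(ModelIntegrityError, match="checksum"):
            ShapeModel.load(path)

    def test_wrong_version_rejected(self, model_small, tmp_path):
        path = model_small.save(tmp_path / "model.h5")
        with h5py.File(path, "r+") as f:
            f.attrs["format_version"] = 999
        with pytest.raises(ModelIntegrityError, match="version"):
            ShapeModel.load(path)


class TestTwoPass:
    @pytest.fixture(scope="class")
    def two_pass_setup(self):
        template, _, lm_idx = make_template(500)
        modes = default_modes(template)
        pop = generate_population(template, modes, 8, 0.0, seed=4,
                                  landmark_indices=lm_idx)
        from shapecomplete import RegistrationSchedule
        schedule = RegistrationSchedule.from_lists(
            [80.0, 40.0], [10.0, 10.0], [40, 100], [12, 12], [1.0, 1.0])
        pass1_aligned, pass1_mean = gpa(pop.meshes)
        pass1 = build_ssm(pass1_aligned)
        model = two_pass_build(pop.meshes, template, schedule, seed=0)
        return pass1, model

    def test_pass2_mean_stable(self, two_pass_setup):
        pass1, model = two_pass_setup
        rms = np.sqrt(((model.mean - pass1.mean) ** 2)
                      .reshape(-1, 3).sum(axis=1).mean())
        assert rms < 0.1

    def test_pass2_satisfies_model_invariants(self, two_pass_setup):
        _, model = two_pass_setup
        gram = model.basis.T @ model.basis
        assert np.abs(gram - np.eye(model.n_components)).max() < 1e-8
        assert (np.diff(model.eigenvalues) <= 1e-9).all()
        assert model.n_components <= 7          # n_training - 1

    def test_total_variance_within_5pct_between_passes(self, two_pass_setup):
        pass1, model = two_pass_setup
        assert model.eigenvalues.sum() == pytest.approx(
            pass1.eigenvalues.sum(), rel=0.05)
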