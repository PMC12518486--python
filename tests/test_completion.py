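"""Kernel augmentation, GP posterior (vs dense oracles), completion, grid."""

import numpy as np
import pytest

from shapecomplete import (KernelParams, PartialObservation, ValidationError,
                           augment_model, complete, cut_by_length_fraction,
                           grid_search, posterior)
from shapecomplete.completion import CompletionEngine, _proximal_submesh
from shapecomplete.geometry import surface_distance
from shapecomplete.lowrank import isotropic_kernel, nystrom_eigenpairs


class TestKernel:
    def test_zero_lag_equals_scale(self):
        x = np.array([[1.0, 2.0, 3.0]])
        assert isotropic_kernel(x, x, sigma=100.0, scale=5.0)[0, 0] == 5.0

    def test_value_at_sigma_lag(self):
        x = np.array([[0.0, 0.0, 0.0]])
        y = np.array([[100.0, 0.0, 0.0]])
        k = isotropic_kernel(x, y, sigma=100.0, scale=5.0)[0, 0]
        assert k == pytest.approx(5.0 / np.e, rel=1e-12)

    def test_nystrom_matches_dense_eigendecomposition(self):
        # with landmarks = all points the Nystrom construction is exact
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=30.0, size=(30, 3))
        K = isotropic_kernel(pts, pts, sigma=50.0, scale=5.0)
        dense = np.sort(np.linalg.eigvalsh(K))[::-1]
        lam, V = nystrom_eigenpairs(pts, 50.0, 5.0, n_components=30,
                                    n_landmarks=30, seed=0)
        assert np.abs(lam - dense[:len(lam)]).max() / dense[0] < 0.01
        # eigenvector property: K v = lambda v
        for i in range(5):
            assert np.abs(K @ V[:, i] - lam[i] * V[:, i]).max() < 1e-8 * dense[0]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            KernelParams(noise=0.0, sigma=100.0, scale=5.0)


class TestAugment:
    def test_augmented_model_invariants(self, model_small):
        aug = augment_model(model_small, KernelParams(20, 100, 5),
                            n_basis=30, seed=0)
        gram = aug.basis.T @ aug.basis
        assert np.abs(gram - np.eye(aug.n_components)).max() < 1e-8
        assert (np.diff(aug.eigenvalues) <= 1e-9 * aug.eigenvalues[0]).all()
        assert aug.n_components > model_small.n_components

    def test_covariance_is_sum_of_parts(self, toy_model):
        # exact check on a toy model: augmented covariance equals
        # SSM covariance + the dense isotropic kernel (x I3)
        params = KernelParams(20, 40, 3)
        aug = augment_model(toy_model, params, n_basis=30, seed=0,
                            n_landmarks=toy_model.n_vertices)
        pts = toy_model.mean.reshape(-1, 3)
        Kd = isotropic_kernel(pts, pts, params.sigma, params.scale)
        n3 = 3 * toy_model.n_vertices
        dense = np.zeros((n3, n3))
        for d in range(3):
            dense[d::3, d::3] = Kd
        dense += (toy_model.basis * toy_model.eigenvalues) @ toy_model.basis.T
        approx = (aug.basis * aug.eigenvalues) @ aug.basis.T
        assert np.abs(approx - dense).max() < 1e-8 * np.abs(dense).max()


class TestPosterior:
    def test_matches_dense_normal_equations(self, toy_model):
        rng = np.random.default_rng(1)
        obs_idx = np.array([0, 2, 3, 5, 7, 9])
        obs_pos = toy_model.mean.reshape(-1, 3)[obs_idx] + \
            rng.normal(scale=1.0, size=(6, 3))
        noise_var = 2.5
        result = posterior(toy_model, PartialObservation(obs_idx, obs_pos),
                           noise_var)
        # independent dense solve
        rows = (3 * obs_idx[:, None] + np.arange(3)).ravel()
        Q = (toy_model.basis * np.sqrt(toy_model.eigenvalues))[rows]
        y = obs_pos.ravel() - toy_model.mean[rows]
        alpha = np.linalg.solve(Q.T @ Q + noise_var * np.eye(3), Q.T @ y)
        assert np.abs(result.coefficients - alpha).max() < 1e-8
        cov = noise_var * np.linalg.inv(Q.T @ Q + noise_var * np.eye(3))
        assert np.abs(result.coefficient_covariance - cov).max() < 1e-8

    def test_matches_dense_gp_posterior(self, toy_model):
        # push-through identity: low-rank coefficient solve equals the dense
        # function-space GP posterior restricted to the model subspace
        rng = np.random.default_rng(4)
        obs_idx = np.arange(8)
        obs_pos = toy_model.mean.reshape(-1, 3)[obs_idx] + \
            rng.normal(scale=0.5, size=(8, 3))
        noise_var = 1.5
        result = posterior(toy_model, PartialObservation(obs_idx, obs_pos),
                           noise_var)
        rows = (3 * obs_idx[:, None] + np.arange(3)).ravel()
        Qf = toy_model.basis * np.sqrt(toy_model.eigenvalues)
        C = Qf @ Qf.T
        y = obs_pos.ravel() - toy_model.mean[rows]
        dense_pred = toy_model.mean + C[:, rows] @ np.linalg.solve(
            C[np.ix_(rows, rows)] + noise_var * np.eye(len(rows)), y)
        assert np.abs(result.mesh.vertices.ravel() - dense_pred).max() < 1e-8

    def test_interpolation_limit_recovers_coefficients(self, model_small):
        c_true = 0.7 * np.ones(model_small.n_components)
        shape = model_small.sample_shape(c_true)
        obs = PartialObservation(np.arange(model_small.n_vertices),
                                 shape.vertices)
        result = posterior(model_small, obs, 1e-10)
        assert np.abs(result.coefficients - c_true).max() < 1e-6

    def test_prior_limit_returns_mean(self, model_small):
        shape = model_small.sample_shape(np.ones(model_small.n_components))
        obs = PartialObservation(np.arange(model_small.n_vertices),
                                 shape.vertices)
        result = posterior(model_small, obs, 1e12)
        assert np.abs(result.coefficients).max() < 1e-6
        assert np.abs(result.mesh.vertices.ravel() - model_small.mean).max() \
            < 1e-4

    def test_posterior_mean_linear_in_observations(self, toy_model):
        obs_idx = np.array([1, 4, 6, 8])
        base = toy_model.mean.reshape(-1, 3)[obs_idx]
        delta = np.full((4, 3), 0.5)
        r1 = posterior(toy_model, PartialObservation(obs_idx, base + delta), 2.0)
        r2 = posterior(toy_model, PartialObservation(obs_idx, base + 2 * delta),
                       2.0)
        assert np.abs(r2.coefficients - 2 * r1.coefficients).max() < 1e-10

    def test_observation_shrinks_predictive_sd(self, toy_model):
        obs_idx = np.array([0, 1, 2, 3, 4])
        obs_pos = toy_model.mean.reshape(-1, 3)[obs_idx]
        result = posterior(toy_model, PartialObservation(obs_idx, obs_pos), 1.0)
        prior_var = ((toy_model.basis ** 2) @ toy_model.eigenvalues)
        prior_sd = np.sqrt(prior_var.reshape(-1, 3).sum(axis=1))
        assert (result.per_vertex_sd <= prior_sd + 1e-9).all()


class TestComplete:
    def test_mean_shape_input_is_fixed_point(self, model_at_scale):
        prox, _ = _proximal_submesh(model_at_scale.mean_mesh(), 0.88)
        result = complete(model_at_scale, prox, KernelParams(20, 100, 5))
        mean_mesh = model_at_scale.mean_mesh()
        _, distal = cut_by_length_fraction(mean_mesh, 0.88)
        err = result.mesh.vertices[distal.indices] - \
            mean_mesh.vertices[distal.indices]
        assert np.sqrt((err ** 2).sum(axis=1).mean()) < 0.1

    def test_model_sampled_shape_distal_error(self, model_at_scale):
        rng = np.random.default_rng(17)
        c = rng.standard_normal(model_at_scale.n_components)
        samp = model_at_scale.sample_shape(c)
        prox, _ = _proximal_submesh(samp, 0.88)
        result = complete(model_at_scale, prox, KernelParams(20, 100, 5))
        _, distal = cut_by_length_fraction(result.mesh, 0.88)
        d = surface_distance(result.mesh.vertices[distal.indices], samp)
        assert np.sqrt((d ** 2).mean()) < 0.5

    def test_predicted_topology_is_model_topology(self, model_small):
        prox, _ = _proximal_submesh(model_small.mean_mesh(), 0.88)
        result = complete(model_small, prox, KernelParams(20, 100, 5),
                          n_basis=30)
        assert (result.mesh.faces == model_small.reference.faces).all()


class TestGridSearch:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        from shapecomplete import build_ssm, default_modes, \
            generate_population, make_template
        template, _, lm_idx = make_template(400)
        modes = default_modes(template)
        pop = generate_population(template, modes, 20, 0.1, seed=9,
                                  landmark_indices=lm_idx)
        model = build_ssm(pop.meshes[:16])
        return model, pop.meshes[16:18]

    def test_printed_grid_has_72_triples(self, tiny_setup):
        model, validation = tiny_setup
        best, table = grid_search(model, validation, n_basis=24, seed=0)
        assert len(table) == 4 * 6 * 3
        assert len(table.drop_duplicates(["noise", "sigma", "scale"])) == 72

    def test_returned_best_is_table_argmin(self, tiny_setup):
        model, validation = tiny_setup
        grid = {"noise": [5.0, 20.0], "sigma": [60.0, 120.0], "scale": [5.0]}
        best, table = grid_search(model, validation, grid=grid, n_basis=24,
                                  seed=0)
        row = table[(table.noise == best.noise) & (table.sigma == best.sigma)
                    & (table.scale == best.scale)]
        assert row["mean_error_mm"].iloc[0] == table["mean_error_mm"].min()

    def test_empty_validation_rejected(self, tiny_setup):
        model, _ = tiny_setup
        with pytest.raises(ValidationError):
            grid_search(model, [])
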