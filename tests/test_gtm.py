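import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gtmphen import gtm
from gtmphen.gtm import GTMModel, LatentGrid, RBFBasis


def naive_log_likelihood(model, X):
    """Direct, unstabilised evaluation of the mixture log-likelihood."""
    Y = gtm.reference_vectors(model)
    K, D = Y.shape
    total = 0.0
    for x in X:
        p = 0.0
        for y in Y:
            p += (model.beta / (2 * np.pi)) ** (D / 2) * np.exp(
                -model.beta / 2 * np.sum((x - y) ** 2))
        total += np.log(p / K)
    return total


def random_small_model(rng, N=12, K=9, D=3):
    side = int(np.sqrt(K))
    grid = gtm.build_latent_grid(side)
    basis = gtm.build_rbf_basis(grid, 2)
    W = rng.normal(size=(D, basis.phi.shape[1]))
    model = GTMModel(grid=grid, basis=basis, W=W, beta=rng.uniform(0.5, 3.0), lam=1.0)
    X = rng.normal(size=(N, D))
    return model, X


class TestLatentGrid:
    def test_grid_node_count(self):
        assert gtm.build_latent_grid(15).K == 225

    def test_side2_corners(self):
        nodes = gtm.build_latent_grid(2).nodes
        assert {tuple(n) for n in nodes} == {(-1, -1), (-1, 1), (1, -1), (1, 1)}

    def test_side3_has_centre(self):
        nodes = gtm.build_latent_grid(3).nodes
        assert any(np.array_equal(n, [0.0, 0.0]) for n in nodes)

    def test_row_major_from_top_left(self):
        nodes = gtm.build_latent_grid(3).nodes
        assert np.array_equal(nodes[0], [-1.0, 1.0])
        assert np.array_equal(nodes[-1], [1.0, -1.0])

    def test_small_side_rejected(self):
        with pytest.raises(ValueError):
            gtm.build_latent_grid(1)


class TestRBFBasis:
    def test_count_and_bias(self):
        grid = gtm.build_latent_grid(15)
        basis = gtm.build_rbf_basis(grid, 14)
        assert basis.M == 196
        assert basis.phi.shape == (225, 197)
        assert np.all(basis.phi[:, -1] == 1.0)

    def test_coincident_centre_activation_is_one(self):
        grid = gtm.build_latent_grid(3)
        basis = gtm.build_rbf_basis(grid, 3)  # centres coincide with nodes
        for l in range(9):
            assert basis.phi[l, l] == pytest.approx(1.0)

    def test_cell_by_cell_formula(self):
        grid = gtm.build_latent_grid(4)
        basis = gtm.build_rbf_basis(grid, 3, width_factor=1.5)
        for l in range(grid.K):
            for j in range(basis.M):
                d2 = np.sum((grid.nodes[l] - basis.centres[j]) ** 2)
                expect = np.exp(-d2 / (2 * basis.width**2))
                assert basis.phi[l, j] == pytest.approx(expect, abs=1e-12)
        assert np.all(basis.phi[:, :-1] > 0) and np.all(basis.phi[:, :-1] <= 1)

    def test_bad_width_rejected(self):
        grid = gtm.build_latent_grid(3)
        with pytest.raises(ValueError):
            gtm.build_rbf_basis(grid, 2, width_factor=0.0)


class TestInitialize:
    def test_pca_init_lies_in_data_plane(self):
        rng = np.random.default_rng(0)
        basis2d = rng.normal(size=(2, 5))
        Z = rng.normal(size=(100, 2))
        X = Z @ basis2d  # exactly planar, D=5
        grid = gtm.build_latent_grid(4)
        basis = gtm.build_rbf_basis(grid, 3)
        model = gtm.initialize(X, grid, basis, method="pca")
        Y = gtm.reference_vectors(model)
        # residual after projecting onto the data plane is ~0
        Q, _ = np.linalg.qr(basis2d.T)
        resid = (Y - X.mean(0)) - ((Y - X.mean(0)) @ Q) @ Q.T
        assert np.abs(resid).max() < 1e-6

    def test_random_init_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        grid = gtm.build_latent_grid(3)
        basis = gtm.build_rbf_basis(grid, 2)
        a = gtm.initialize(X, grid, basis, method="random", seed=11)
        b = gtm.initialize(X, grid, basis, method="random", seed=11)
        assert np.array_equal(a.W, b.W)

    def test_pca_init_translation_equivariant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 4))
        shift = np.array([5.0, -3.0, 2.0, 10.0])
        grid = gtm.build_latent_grid(4)
        basis = gtm.build_rbf_basis(grid, 3)
        Y0 = gtm.reference_vectors(gtm.initialize(X, grid, basis))
        Y1 = gtm.reference_vectors(gtm.initialize(X + shift, grid, basis))
        np.testing.assert_allclose(Y1, Y0 + shift, atol=1e-6)

    def test_rank1_data_rejected_with_hint(self):
        x = np.arange(50.0)
        X = np.column_stack([x, 2 * x, -x])
        grid = gtm.build_latent_grid(3)
        basis = gtm.build_rbf_basis(grid, 2)
        with pytest.raises(ValueError, match="random"):
            gtm.initialize(X, grid, basis, method="pca")


class TestEStep:
    def _two_component_1d(self):
        grid = LatentGrid(side=1, nodes=np.array([[0.0, 0.0], [0.5, 0.5]]))
        basis = RBFBasis(centres=np.zeros((1, 2)), width=1.0, phi=np.eye(2))
        return GTMModel(grid=grid, basis=basis, W=np.array([[0.0, 2.0]]),
                        beta=1.0, lam=0.0)

    def test_single_component_responsibility_is_one(self):
        grid = LatentGrid(side=1, nodes=np.zeros((1, 2)))
        basis = gtm.build_rbf_basis(grid, 0)
        model = GTMModel(grid=grid, basis=basis, W=np.array([[1.0], [2.0]]),
                         beta=1.0, lam=0.0)
        resp, _ = gtm.e_step(model, np.random.default_rng(0).normal(size=(5, 2)))
        assert np.all(resp.R == 1.0)

    def test_two_gaussian_hand_values(self):
        model = self._two_component_1d()
        resp, ll = gtm.e_step(model, np.array([[0.5]]))
        e = np.exp(-1.0)
        np.testing.assert_allclose(resp.R[0], [1 / (1 + e), e / (1 + e)], atol=1e-9)
        assert ll == pytest.approx(-1.4238, abs=1e-4)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_direct_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        model, X = random_small_model(rng, N=min(20, 5 + seed * 2))
        _, ll = gtm.e_step(model, X)
        assert ll == pytest.approx(naive_log_likelihood(model, X), abs=1e-6)

    def test_nonfinite_data_rejected(self):
        rng = np.random.default_rng(0)
        model, X = random_small_model(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            gtm.e_step(model, X)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_rows_are_probability_vectors(self, seed):
        rng = np.random.default_rng(seed)
        model, X = random_small_model(rng)
        resp, _ = gtm.e_step(model, X)
        assert np.all(resp.R >= 0)
        np.testing.assert_allclose(resp.R.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    @pytest.mark.parametrize("seed", range(30))
    def test_em_update_never_decreases_penalised_objective(self, seed):
        rng = np.random.default_rng(seed)
        model, X = random_small_model(rng, N=20)
        resp, ll = gtm.e_step(model, X)
        before = gtm.penalised_objective(model, ll)
        new = gtm.m_step(model, X, resp)
        _, ll2 = gtm.e_step(new, X)
        after = gtm.penalised_objective(new, ll2)
        assert after >= before - 1e-8

    def test_degenerate_single_cluster_converges_to_centroid(self):
        c = np.array([3.0, -2.0])
        X = np.tile(c, (10, 1))
        grid = LatentGrid(side=1, nodes=np.zeros((1, 2)))
        basis = gtm.build_rbf_basis(grid, 0)
        model = GTMModel(grid=grid, basis=basis, W=np.zeros((2, 1)), beta=1.0, lam=0.0)
        for _ in range(5):
            resp, _ = gtm.e_step(model, X)
            model = gtm.m_step(model, X, resp)
        np.testing.assert_allclose(gtm.reference_vectors(model)[0], c, atol=1e-10)
        assert 1.0 / model.beta == pytest.approx(1e-8)  # floored, not divergent

    def test_large_lambda_shrinks_weights_monotonically(self):
        rng = np.random.default_rng(4)
        model, X = random_small_model(rng, N=30)
        resp, _ = gtm.e_step(model, X)
        norms = []
        for lam in [1.0, 10.0, 1e3, 1e6]:
            m = GTMModel(grid=model.grid, basis=model.basis, W=model.W,
                         beta=model.beta, lam=lam)
            m2 = gtm.m_step(m, X, resp)
            norms.append(np.linalg.norm(m2.W[:, :-1]))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3

    def test_singular_normal_matrix_advises_regularisation(self):
        # more basis columns than nodes -> rank-deficient normal matrix
        rng = np.random.default_rng(0)
        grid = gtm.build_latent_grid(2)
        basis = gtm.build_rbf_basis(grid, 3)          # 10 columns, K=4
        model = GTMModel(grid=grid, basis=basis,
                         W=rng.normal(size=(3, 10)), beta=1.0, lam=0.0)
        X = rng.normal(size=(8, 3))
        resp, _ = gtm.e_step(model, X)
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            gtm.m_step(model, X, resp)


class TestFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_objective_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 4)) + rng.integers(0, 2, size=(60, 1)) * 4
        _, trace = gtm.fit(X, side=4, rbf_side=3, seed=seed, max_iter=60)
        obj = np.array(trace.objective_per_iteration)
        assert np.all(np.diff(obj) >= -1e-8)

    def test_single_gaussian_limit_matches_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 1.5, size=(50, 3))
        grid = LatentGrid(side=1, nodes=np.zeros((1, 2)))
        basis = gtm.build_rbf_basis(grid, 0)
        model = gtm.initialize(X, grid, basis, method="random", seed=0, lam=0.0)
        for _ in range(60):
            resp, _ = gtm.e_step(model, X)
            model = gtm.m_step(model, X, resp)
        np.testing.assert_allclose(gtm.reference_vectors(model)[0], X.mean(0),
                                   atol=1e-8)
        expect_var = np.sum((X - X.mean(0)) ** 2) / X.size
        assert 1.0 / model.beta == pytest.approx(expect_var, abs=1e-8)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 5))
        m1, t1 = gtm.fit(X, side=5, rbf_side=3, seed=9, max_iter=40)
        m2, t2 = gtm.fit(X, side=5, rbf_side=3, seed=9, max_iter=40)
        assert np.array_equal(m1.W, m2.W) and m1.beta == m2.beta
        assert t1.objective_per_iteration == t2.objective_per_iteration

    def test_nonconvergence_reported_not_raised(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        _, trace = gtm.fit(X, side=4, rbf_side=3, max_iter=2, tol=1e-12)
        assert trace.converged is False


class TestReferenceVectorsAndAssignment:
    def test_matches_per_node_evaluation(self, smooth_fit):
        model = smooth_fit["model"]
        Y = gtm.reference_vectors(model)
        for l in [0, 7, 33, model.K - 1]:
            y_l = model.W @ model.basis.design(model.grid.nodes[l])[0]
            np.testing.assert_allclose(Y[l], y_l, rtol=1e-12)

    def test_bias_only_basis_gives_identical_rows(self):
        grid = gtm.build_latent_grid(3)
        basis = gtm.build_rbf_basis(grid, 0)
        model = GTMModel(grid=grid, basis=basis, W=np.array([[2.0], [3.0]]),
                         beta=1.0, lam=0.0)
        Y = gtm.reference_vectors(model)
        assert np.all(Y == Y[0])

    def test_point_at_reference_vector_assigned_to_it(self, smooth_fit):
        model, X = smooth_fit["model"], smooth_fit["X"]
        Y = gtm.reference_vectors(model)
        labels = gtm.assign_micro(model, Y[[10, 40]])
        # the node's own vector is its nearest reference vector in a smooth fit
        d = np.linalg.norm(Y[[10, 40], None, :] - Y[None, :, :], axis=2)
        assert list(labels) == list(np.argmin(d, axis=1))

    def test_tie_broken_by_lowest_index(self):
        grid = LatentGrid(side=1, nodes=np.zeros((8, 2)))
        basis = RBFBasis(centres=np.zeros((1, 2)), width=1.0, phi=np.eye(8))
        W = np.zeros((1, 8))
        W[0, 3] = W[0, 7] = 1.0     # nodes 3 and 7 tie for x=1
        model = GTMModel(grid=grid, basis=basis, W=W, beta=1.0, lam=0.0)
        assert gtm.assign_micro(model, np.array([[1.0]]))[0] == 3

    def test_argmax_equals_nearest_reference_vector(self, smooth_fit):
        model, X = smooth_fit["model"], smooth_fit["X"]
        labels = gtm.assign_micro(model, X)
        Y = gtm.reference_vectors(model)
        from scipy.spatial.distance import cdist
        brute = np.argmin(cdist(X, Y), axis=1)
        assert np.array_equal(labels, brute)


class TestSerialisation:
    def test_round_trip_bit_exact(self, tmp_path, smooth_fit):
        model = smooth_fit["model"]
        path = tmp_path / "model.json"
        gtm.save_model(model, path, extra={"scaler": {"names": ["a"]}})
        loaded, extra = gtm.load_model(path)
        assert np.array_equal(loaded.W, model.W)
        assert loaded.beta == model.beta and loaded.lam == model.lam
        assert np.array_equal(loaded.basis.phi, model.basis.phi)
        assert extra["scaler"] == {"names": ["a"]}
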