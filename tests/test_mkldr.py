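import numpy as np
import pytest
import scipy.linalg

from fmkldr import mcmo
from fmkldr.kernels import kernel_grid, kernel_slice
from fmkldr.mkldr import (
    AffinityPair,
    lda_affinities,
    optimize_A,
    optimize_beta,
    project,
    project_training,
    scatter_A,
    scatter_beta,
    train_fmkldr,
)
from fmkldr.preprocess import drop_incomplete_features, minmax_rescale
from fmkldr.simdata import SimSpec, make_multiview_cohort

from conftest import random_psd_stack


def naive_scatter(stack, W, A=None, beta=None):
    """Oracle: the literal double sum over all (i, j) pairs, composed from
    plain dense products with no chain ordering or Laplacian identity."""
    N, M = stack.n_samples, stack.n_kernels
    slices = [kernel_slice(stack, i) for i in range(N)]
    S = np.zeros((M, M) if A is not None else (N, N))
    for i in range(N):
        for j in range(N):
            d = slices[i] - slices[j]
            if A is not None:
                S += W[i, j] * (d.T @ A) @ (A.T @ d)
            else:
                u = d @ beta
                S += W[i, j] * np.outer(u, u)
    return S


class TestLdaAffinities:
    def test_two_balanced_classes(self):
        aff = lda_affinities(np.array(["a", "a", "b", "b"]))
        expected = np.zeros((4, 4))
        expected[:2, :2] = 0.5
        expected[2:, 2:] = 0.5
        np.testing.assert_allclose(aff.W, expected)
        np.testing.assert_allclose(aff.W_prime, 0.25)
        np.testing.assert_allclose(aff.W.sum(axis=1), 1.0)

    def test_unbalanced_classes(self):
        labels = np.array(["a"] * 3 + ["b"] * 6)
        aff = lda_affinities(labels)
        assert aff.W[0, 1] == pytest.approx(1 / 3)
        assert aff.W[4, 5] == pytest.approx(1 / 6)
        assert aff.W[0, 4] == 0.0
        np.testing.assert_allclose(aff.W_prime, 1 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_affinities(np.array(["a", "a", "a"]))

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            lda_affinities(np.array(["a", "a", "b"]))


class TestScatterMatrices:
    def test_zero_affinities_give_zero_scatter(self, rng):
        stack = random_psd_stack(rng, 4, 2)
        aff = AffinityPair(np.zeros((4, 4)), np.zeros((4, 4)))
        A = rng.normal(size=(4, 2))
        S, Sp = scatter_A(stack, A, aff)
        np.testing.assert_allclose(S, 0.0)
        np.testing.assert_allclose(Sp, 0.0)

    def test_zero_beta_gives_zero_scatter(self, rng):
        stack = random_psd_stack(rng, 4, 2)
        aff = lda_affinities(np.array(["a", "a", "b", "b"]))
        S, _ = scatter_beta(stack, np.zeros(2), aff)
        np.testing.assert_allclose(S, 0.0)

    def test_fast_path_matches_double_sum_oracle(self, rng):
        stack = random_psd_stack(rng, 6, 2)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        aff = lda_affinities(labels)
        A = rng.normal(size=(6, 2))
        beta = rng.normal(size=2)
        for W in (aff.W, aff.W_prime):
            np.testing.assert_allclose(
                naive_scatter(stack, W, A=A),
                scatter_A(stack, A, AffinityPair(W, W))[0],
                rtol=1e-8,
            )
            np.testing.assert_allclose(
                naive_scatter(stack, W, beta=beta),
                scatter_beta(stack, beta, AffinityPair(W, W))[0],
                rtol=1e-8,
            )

    def test_pairwise_path_with_chain_order_matches_oracle(self, rng):
        stack = random_psd_stack(rng, 5, 2)
        aff = lda_affinities(np.array(["a", "a", "b", "b", "b"]))
        A = rng.normal(size=(5, 1))
        beta = rng.normal(size=2)
        order_A = mcmo.chain_order((2, 5, 1, 5, 2))
        order_b = mcmo.chain_order((5, 2, 1, 2, 5))
        np.testing.assert_allclose(
            scatter_A(stack, A, aff, order_A, method="pairwise")[0],
            naive_scatter(stack, aff.W, A=A),
            rtol=1e-8,
        )
        np.testing.assert_allclose(
            scatter_beta(stack, beta, aff, order_b, method="pairwise")[0],
            naive_scatter(stack, aff.W, beta=beta),
            rtol=1e-8,
        )

    def test_quadratic_homogeneity_in_A(self, rng):
        stack = random_psd_stack(rng, 4, 2)
        aff = lda_affinities(np.array(["a", "a", "b", "b"]))
        A = rng.normal(size=(4, 1))
        S1, _ = scatter_A(stack, A, aff)
        S2, _ = scatter_A(stack, 2 * A, aff)
        np.testing.assert_allclose(S2, 4 * S1, rtol=1e-10)

    def test_single_kernel_beta_scatter_reduces_to_column_form(self, rng):
        stack = random_psd_stack(rng, 4, 1)
        aff = lda_affinities(np.array(["a", "a", "b", "b"]))
        S, _ = scatter_beta(stack, np.ones(1), aff)
        K = stack.kernels[0]
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                d = K[:, i] - K[:, j]
                expected += aff.W[i, j] * np.outer(d, d)
        np.testing.assert_allclose(S, expected, rtol=1e-8)


class TestEigenSteps:
    def test_identity_pencil(self):
        A = optimize_A(np.eye(3), np.eye(3), 2)
        np.testing.assert_allclose(A.T @ A, np.eye(2), atol=1e-10)

    def test_diagonal_pencil_picks_smallest(self):
        A = optimize_A(np.diag([3.0, 2.0, 1.0]), np.eye(3), 1)
        np.testing.assert_allclose(np.abs(A.ravel()), [0, 0, 1], atol=1e-10)

    def test_matches_cholesky_whitened_solver(self, rng):
        """Oracle: reduce to a standard symmetric problem via Cholesky of
        the (PD) constraint matrix and compare eigenvalues."""
        X = rng.normal(size=(6, 8))
        S = X @ X.T
        Y = rng.normal(size=(6, 8))
        Sp = Y @ Y.T + 0.5 * np.eye(6)
        L = np.linalg.cholesky(Sp)
        C = np.linalg.solve(L, np.linalg.solve(L, S.T).T)
        ref = np.sort(np.linalg.eigvalsh(C))
        A = optimize_A(S, Sp, 2)
        lam = np.diag(A.T @ S @ A)  # A is Sp-orthonormal, so these are eigenvalues
        np.testing.assert_allclose(np.sort(lam), ref[:2], rtol=1e-7)
        np.testing.assert_allclose(A.T @ Sp @ A, np.eye(2), atol=1e-7)

    def test_single_kernel_beta_is_one(self):
        np.testing.assert_allclose(optimize_beta(np.eye(1), np.eye(1)), [1.0])

    def test_diagonal_beta_pencil(self):
        beta = optimize_beta(np.diag([5.0, 1.0]), np.eye(2))
        np.testing.assert_allclose(beta, [0.0, 1.0], atol=1e-10)

    def test_beta_eigen_residual(self, rng):
        X = rng.normal(size=(4, 6))
        S = X @ X.T
        Y = rng.normal(size=(4, 6))
        Sp = Y @ Y.T + 0.5 * np.eye(4)
        beta = optimize_beta(S, Sp, nonneg=False)
        lam = (beta @ S @ beta) / (beta @ Sp @ beta)
        resid = np.linalg.norm(S @ beta - lam * (Sp @ beta))
        assert resid <= 1e-8 * np.linalg.norm(S)
        assert np.linalg.norm(beta) == pytest.approx(1.0)

    def test_nonneg_projection_yields_convex_style_weights(self, rng):
        X = rng.normal(size=(5, 7))
        S = X @ X.T
        Y = rng.normal(size=(5, 7))
        Sp = Y @ Y.T + 0.5 * np.eye(5)
        beta = optimize_beta(S, Sp, nonneg=True)
        assert np.all(beta >= 0)
        assert np.linalg.norm(beta) == pytest.approx(1.0)


def small_training_problem(seed=3, n_views=2, effect=(4.0, 0.0)):
    spec = SimSpec(
        class_sizes=(12, 12), n_views=n_views, dims=(10,) * n_views,
        effect_size=effect, scale=(1.0,) * n_views, seed=seed,
    )
    views, labels = make_multiview_cohort(spec)
    views = [minmax_rescale(drop_incomplete_features(v)) for v in views]
    return kernel_grid(views, (1.0,)), labels


class TestTraining:
    def test_chain_ordering_invoked_exactly_twice(self, monkeypatch):
        stack, labels = small_training_problem()
        calls = []
        real = mcmo.chain_order
        monkeypatch.setattr(mcmo, "chain_order", lambda d: calls.append(d) or real(d))
        train_fmkldr(stack, labels, P=2, n_iter=4)
        assert len(calls) == 2

    def test_single_kernel_beta_stays_one(self):
        stack, labels = small_training_problem(n_views=1, effect=(4.0,))
        model = train_fmkldr(stack, labels, P=2, n_iter=3, init="beta")
        np.testing.assert_allclose(model.beta, [1.0])

    def test_embedding_constraint_normalization(self):
        stack, labels = small_training_problem()
        model = train_fmkldr(stack, labels, P=2, n_iter=3)
        aff = lda_affinities(labels)
        _, S_bp = scatter_beta(stack, model.beta, aff)
        np.testing.assert_allclose(model.A.T @ S_bp @ model.A, np.eye(2), atol=1e-6)

    def test_history_length_and_beta_norm(self):
        stack, labels = small_training_problem()
        model = train_fmkldr(stack, labels, P=2, n_iter=5)
        assert len(model.history) == 5
        assert np.linalg.norm(model.beta) == pytest.approx(1.0)

    def test_sample_permutation_invariance(self, rng):
        # P=1 with two classes keeps the bottom eigenvalue simple, so the
        # embedding is identified up to sign; larger P hits degenerate
        # eigenspaces where only the spanned subspace is identified
        stack, labels = small_training_problem()
        model = train_fmkldr(stack, labels, P=1, n_iter=3)
        Z = project_training(model, stack)
        perm = rng.permutation(stack.n_samples)
        from fmkldr.kernels import KernelStack

        permuted = KernelStack(
            [K[np.ix_(perm, perm)] for K in stack.kernels],
            list(stack.specs),
            [stack.sample_ids[i] for i in perm],
        )
        model_p = train_fmkldr(permuted, labels[perm], P=1, n_iter=3)
        Z_p = project_training(model_p, permuted)
        inv = np.argsort(perm)
        col, ref = Z_p[inv][:, 0], Z[:, 0]
        assert np.allclose(col, ref, atol=1e-6) or np.allclose(-col, ref, atol=1e-6)

    def test_kernel_scale_leaves_beta_ranking_unchanged(self):
        from fmkldr.kernels import KernelStack

        stack, labels = small_training_problem()
        model = train_fmkldr(stack, labels, P=2, n_iter=3)
        scaled = KernelStack(
            [7.5 * K for K in stack.kernels], list(stack.specs), list(stack.sample_ids)
        )
        model_s = train_fmkldr(scaled, labels, P=2, n_iter=3)
        np.testing.assert_array_equal(np.argsort(model.beta), np.argsort(model_s.beta))

    def test_nearest_centroid_separates_classes_at_large_effect(self):
        """On well-separated synthetic data the embedded classes are
        linearly separable by their centroids, across seeds."""
        for seed in range(10):
            stack, labels = small_training_problem(seed=seed)
            model = train_fmkldr(stack, labels, P=2, n_iter=5)
            Z = project_training(model, stack)
            cents = {c: Z[labels == c].mean(axis=0) for c in np.unique(labels)}
            pred = [
                min(cents, key=lambda c: np.linalg.norm(z - cents[c])) for z in Z
            ]
            assert np.mean(np.array(pred) == labels) == 1.0


class TestProjection:
    def test_training_slices_match_project_training(self):
        stack, labels = small_training_problem()
        model = train_fmkldr(stack, labels, P=2, n_iter=3)
        slices = [kernel_slice(stack, i) for i in range(stack.n_samples)]
        np.testing.assert_allclose(
            project(model, slices), project_training(model, stack), atol=1e-10
        )

    def test_zero_beta_projects_to_origin(self):
        stack, labels = small_training_problem()
        model = train_fmkldr(stack, labels, P=2, n_iter=2)
        model.beta = np.zeros_like(model.beta)
        slices = [kernel_slice(stack, i) for i in range(3)]
        np.testing.assert_allclose(project(model, slices), 0.0)

    def test_selection_identity(self, rng):
        stack = random_psd_stack(rng, 5, 1)
        from fmkldr.mkldr import MKLDRModel

        A = np.zeros((5, 1))
        A[0, 0] = 1.0
        model = MKLDRModel(A=A, beta=np.ones(1), P=1,
                           train_sample_ids=stack.sample_ids, specs=stack.specs)
        slices = [kernel_slice(stack, i) for i in range(5)]
        Z = project(model, slices)
        np.testing.assert_allclose(Z.ravel(), stack.kernels[0][0, :])

    def test_bad_slice_shape_rejected(self):
        stack, labels = small_training_problem()
        model = train_fmkldr(stack, labels, P=2, n_iter=2)
        with pytest.raises(ValueError):
            project(model, [np.zeros((3, 3))])


def test_model_roundtrip(tmp_path):
    stack, labels = small_training_problem()
    model = train_fmkldr(stack, labels, P=2, n_iter=3)
    model.save(tmp_path / "model")
    from fmkldr.mkldr import MKLDRModel

    loaded = MKLDRModel.load(tmp_path / "model")
    np.testing.assert_array_equal(loaded.A, model.A)
    np.testing.assert_array_equal(loaded.beta, model.beta)
    assert loaded.specs == model.specs
    assert loaded.train_sample_ids == model.train_sample_ids
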