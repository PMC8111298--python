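"""NNDSVD start, multiplicative steps, objective, fit loop, label assignment."""

import numpy as np
import pytest

from conftest import random_similarity_graph
from lvsnmf.factorization import (
    FitConfig,
    assign_clusters,
    fit,
    lvsnmf_step,
    nndsvd_init,
    objective,
    snmf_step,
)
from lvsnmf.graphs import knn_sparsify, symmetric_normalize
from lvsnmf.vicus import vicus_matrix


def random_symmetric_nonneg(rng, n):
    M = rng.random((n, n))
    A = (M + M.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


class TestNndsvdInit:
    def test_rank_one_psd_case_is_analytic(self):
        # A = v v^T with v = (1, 2, 2): leading singular value 9, unit
        # vector v/3, so the single column of H0 is sqrt(9) * v/3 = v.
        v = np.array([1.0, 2.0, 2.0])
        H0 = nndsvd_init(np.outer(v, v), k=1)
        np.testing.assert_allclose(H0[:, 0], v, atol=1e-12)

    def test_bit_identical_across_calls(self, rng):
        A = random_symmetric_nonneg(rng, 7)
        np.testing.assert_array_equal(nndsvd_init(A, 3), nndsvd_init(A, 3))

    def test_reconstruction_within_slack_of_best_rank_k(self, rng):
        A = random_symmetric_nonneg(rng, 6)
        k = 2
        H0 = nndsvd_init(A, k)
        eigvals, eigvecs = np.linalg.eigh(A)
        order = np.argsort(-np.abs(eigvals))[:k]
        A_k = (eigvecs[:, order] * eigvals[order]) @ eigvecs[:, order].T
        lhs = np.linalg.norm(A - H0 @ H0.T, "fro")
        assert lhs <= np.linalg.norm(A - A_k, "fro") + np.linalg.norm(A_k, "fro")

    def test_invalid_rank_rejected(self, rng):
        A = random_symmetric_nonneg(rng, 5)
        with pytest.raises(ValueError, match="rank"):
            nndsvd_init(A, 6)
        with pytest.raises(ValueError, match="rank"):
            nndsvd_init(A, 0)

    def test_strictly_positive_output(self, rng):
        A = random_symmetric_nonneg(rng, 8)
        assert nndsvd_init(A, 3).min() > 0  # zeros perturbed


class TestSnmfStep:
    def test_exact_factorization_is_fixed_point(self, rng):
        H = rng.random((6, 2)) + 0.1
        A = H @ H.T
        H_new = snmf_step(A, H)
        np.testing.assert_allclose(H_new, H, rtol=1e-12)

    def test_preserves_nonnegativity(self, rng):
        for _ in range(5):
            A = random_symmetric_nonneg(rng, 8)
            H = rng.random((8, 3))
            assert snmf_step(A, H).min() >= 0

    def test_reconstruction_error_nonincreasing_from_nndsvd(self, rng):
        A = random_symmetric_nonneg(rng, 8)
        H = nndsvd_init(A, 2)
        prev = np.linalg.norm(A - H @ H.T, "fro") ** 2
        for _ in range(50):
            H = snmf_step(A, H)
            obj = np.linalg.norm(A - H @ H.T, "fro") ** 2
            assert obj <= prev * (1 + 1e-8)
            prev = obj


class TestLvsnmfStep:
    @pytest.fixture
    def problem(self, rng):
        G = random_similarity_graph(rng, 15)
        sparse = knn_sparsify(G, p=6)
        A = symmetric_normalize(sparse)
        V = vicus_matrix(G, K=5)
        H = nndsvd_init(A, 3)
        return A, sparse, V, H

    def test_zero_regularization_reduces_to_snmf(self, problem):
        A, G, V, H = problem
        out = lvsnmf_step(A, H, P=G, V=V, reg_alpha=0.0)
        np.testing.assert_array_equal(out, snmf_step(A, H))

    def test_disabled_terms_reduce_to_snmf(self, problem):
        A, G, V, H = problem
        out = lvsnmf_step(A, H, P=G, V=V, reg_alpha=5.0,
                          use_laplacian=False, use_vicus=False)
        np.testing.assert_array_equal(out, snmf_step(A, H))

    def test_preserves_nonnegativity(self, problem):
        A, G, V, H = problem
        assert lvsnmf_step(A, H, P=G, V=V, reg_alpha=0.5).min() >= 0

    def test_dimension_mismatch_names_offender(self, problem, rng):
        A, G, V, H = problem
        with pytest.raises(ValueError, match="H has"):
            lvsnmf_step(A, rng.random((9, 3)), P=G, V=V)
        bad_P = np.ones((4, 4))
        with pytest.raises(ValueError, match="P has"):
            lvsnmf_step(A, H, P=bad_P, V=V)

    def test_missing_matrices_rejected(self, problem):
        A, G, V, H = problem
        with pytest.raises(ValueError, match="requires the graph"):
            lvsnmf_step(A, H, P=None, V=V, use_laplacian=True)
        with pytest.raises(ValueError, match="requires the Vicus"):
            lvsnmf_step(A, H, P=G, V=None, use_vicus=True)

    def test_full_model_decreases_objective_on_two_blocks(self, rng):
        X = np.vstack([rng.normal(0, 0.4, (10, 3)), rng.normal(6, 0.4, (10, 3))])
        X -= X.min()
        from lvsnmf.graphs import gaussian_kernel_similarity

        G = gaussian_kernel_similarity(np.clip(X, 0, None), d=5)
        sparse = knn_sparsify(G, p=6)
        A = symmetric_normalize(sparse)
        V = vicus_matrix(G, K=5)
        res = fit(A, G=sparse, V=V,
                  config=FitConfig(reg_alpha=0.01, max_iter=200), k=2)
        assert res.objective_trace[-1] <= res.objective_trace[0]


class TestObjective:
    def test_perfect_reconstruction_zero(self, rng):
        H = rng.random((6, 2))
        assert objective(H @ H.T, H, reg_alpha=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_constant_column_annihilated_by_both_regularizers(self, rng):
        G = random_similarity_graph(rng, 10)
        sparse = knn_sparsify(G, p=4)
        A = symmetric_normalize(sparse)
        V = vicus_matrix(G, K=4)
        W, deg = sparse.W, sparse.degrees()
        L = np.diag(deg) - W
        H = np.full((10, 1), 0.7)
        base = objective(A, H, L=L, V=V, reg_alpha=0.0)
        full = objective(A, H, L=L, V=V, reg_alpha=100.0)
        assert full == pytest.approx(base, abs=1e-8)

    def test_matches_scalar_loop_oracle(self, rng):
        n, k = 8, 3
        A = random_symmetric_nonneg(rng, n)
        H = rng.random((n, k))
        M = rng.random((n, n))
        L = (M + M.T) / 2
        Mv = rng.random((n, n))
        Vm = (Mv + Mv.T) / 2
        alpha = 0.37

        recon = sum(
            (A[i, j] - sum(H[i, c] * H[j, c] for c in range(k))) ** 2
            for i in range(n) for j in range(n)
        )
        tr_L = sum(H[i, c] * L[i, j] * H[j, c]
                   for i in range(n) for j in range(n) for c in range(k))
        tr_V = sum(H[i, c] * Vm[i, j] * H[j, c]
                   for i in range(n) for j in range(n) for c in range(k))
        expected = recon + alpha * (tr_L + tr_V)
        got = objective(A, H, L=L, V=Vm, reg_alpha=alpha)
        assert got == pytest.approx(expected, rel=1e-10)


class TestFit:
    def test_recovers_two_perfect_blocks(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        np.fill_diagonal(A, 0.0)
        res = fit(A, config=FitConfig.for_variant("snmf"), k=2)
        assert res.converged
        assert res.n_iter <= 500
        assert len(set(res.labels[:3])) == 1
        assert len(set(res.labels[3:])) == 1
        assert res.labels[0] != res.labels[3]

    def test_identity_like_full_rank_objective_decreases(self):
        A = np.eye(5) * 0.0 + 0.1
        np.fill_diagonal(A, 0.0)
        res = fit(A, config=FitConfig.for_variant("snmf"), k=5)
        assert res.objective_trace[-1] <= res.objective_trace[0]

    def test_variant_codepaths_all_reachable(self, rng):
        G = random_similarity_graph(rng, 12)
        sparse = knn_sparsify(G, p=5)
        A = symmetric_normalize(sparse)
        V = vicus_matrix(G, K=4)
        for variant in ("snmf", "laplacian", "vicus", "lvsnmf"):
            cfg = FitConfig.for_variant(variant, max_iter=50)
            res = fit(A, G=sparse, V=V, config=cfg, k=3)
            assert res.config.variant == variant
            assert np.all(np.isfinite(res.objective_trace))

    def test_affinity_scaling_keeps_labels_on_separated_data(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (8, 3)), rng.normal(7, 0.3, (8, 3))])
        X -= X.min()
        from lvsnmf.graphs import gaussian_kernel_similarity

        G = gaussian_kernel_similarity(np.clip(X, 0, None), d=4)
        sparse = knn_sparsify(G, p=5)
        A = symmetric_normalize(sparse)
        res1 = fit(A.A, config=FitConfig.for_variant("snmf"), k=2)
        res2 = fit(3.0 * A.A, config=FitConfig.for_variant("snmf"), k=2)
        # identical partition; column identity may swap with the SVD's sign
        from lvsnmf.metrics import clustering_accuracy

        assert clustering_accuracy(res1.labels, res2.labels) == 1.0


class TestAssignClusters:
    def test_indicator_matrix_and_tie_rule(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0], [0.2, 0.2]])
        np.testing.assert_array_equal(assign_clusters(H), [0, 1, 0])

    def test_column_permutation_equivariance(self, rng):
        H = rng.random((10, 4))
        perm = rng.permutation(4)
        labels = assign_clusters(H)
        labels_p = assign_clusters(H[:, perm])
        np.testing.assert_array_equal(perm[labels_p], labels)

    def test_all_zero_row_warns_and_assigns_zero(self):
        H = np.array([[0.5, 0.1], [0.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="all-zero"):
            labels = assign_clusters(H)
        assert labels[1] == 0
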