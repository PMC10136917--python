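"""Graphical-lasso fitting, EBIC selection and partial-correlation conversion."""

import numpy as np
import pytest

from tinnet.association import CorrelationMatrix, spearman_matrix
from tinnet.network import (
    ebic_score,
    estimate_network,
    gaussian_loglik,
    glasso_fit,
    precision_to_partial,
)


def random_correlation(p, seed, strength=0.3):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(p, p)) * strength
    K = (A + A.T) / 2
    np.fill_diagonal(K, 1.1 * np.abs(K).sum(axis=1) + 1)
    S = np.linalg.inv(K)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2


class TestGlassoFit:
    def test_identity_input_is_fixed_point(self):
        for lam in (0.0, 0.1, 1.0):
            K = glasso_fit(np.eye(4), lam)
            assert np.allclose(K, np.eye(4), atol=1e-8)

    def test_large_penalty_gives_fully_sparse_offdiagonal(self):
        R = random_correlation(5, seed=1)
        lam = np.abs(R[np.triu_indices(5, 1)]).max()
        K = glasso_fit(R, lam * 1.0001)
        off = K[np.triu_indices(5, 1)]
        assert np.all(np.abs(off) < 1e-8)

    def test_zero_penalty_inverts_matrix(self):
        R = random_correlation(3, seed=2)
        K = glasso_fit(R, 0.0)
        assert np.allclose(K, np.linalg.inv(R), atol=1e-4)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(3), -0.1)


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_empty_network(self):
        W = precision_to_partial(np.diag([1.0, 2.0, 3.0]))
        assert np.allclose(W, 0.0)

    def test_two_node_partial_equals_marginal_correlation(self):
        r = 0.6
        K = np.linalg.inv(np.array([[1.0, r], [r, 1.0]]))
        W = precision_to_partial(K)
        assert W[0, 1] == pytest.approx(r, abs=1e-12)

    def test_entries_bounded_and_sign_flipped(self):
        R = random_correlation(6, seed=3)
        K = np.linalg.inv(R)
        W = precision_to_partial(K)
        off = ~np.eye(6, dtype=bool)
        assert np.all(np.abs(W[off]) < 1)
        nz = off & (np.abs(K) > 1e-12)
        assert np.all(np.sign(W[nz]) == -np.sign(K[nz]))

    def test_nonpositive_diagonal_rejected(self):
        K = np.eye(3)
        K[1, 1] = 0.0
        with pytest.raises(ValueError):
            precision_to_partial(K)


class TestEbic:
    def test_empty_graph_score_is_minus_twice_loglik(self):
        R = random_correlation(4, seed=4)
        K = np.diag(1.0 / np.diag(R))
        n = 200
        assert ebic_score(K, R, n, gamma=0.5) == pytest.approx(
            -2.0 * gaussian_loglik(K, R, n)
        )

    def test_one_extra_edge_costs_logn_plus_gamma_term(self):
        # same K evaluated with and without one off-diagonal entry counted:
        # the penalty difference is exactly log n + 4 gamma log p
        R = random_correlation(4, seed=5)
        n, gamma = 500, 0.5
        K0 = np.diag(1.0 / np.diag(R))
        K1 = K0.copy()
        K1[0, 1] = K1[1, 0] = 1e-7  # one counted edge, negligible loglik shift
        delta = ebic_score(K1, R, n, gamma) - ebic_score(K0, R, n, gamma)
        ll_shift = -2 * (gaussian_loglik(K1, R, n) - gaussian_loglik(K0, R, n))
        assert delta - ll_shift == pytest.approx(
            np.log(n) + 4 * gamma * np.log(4), abs=1e-9
        )

    def test_path_scores_match_brute_force_formula(self):
        R = random_correlation(4, seed=6)
        corr = CorrelationMatrix([f"v{i}" for i in range(4)], R, n=300)
        _, path = estimate_network(corr, n_lambdas=12)
        for lam, K, score in zip(
            path.lambdas, path.precisions, path.ebics
        ):
            E = int(np.sum(np.abs(K[np.triu_indices(4, 1)]) > 1e-8))
            sign, logdet = np.linalg.slogdet(K)
            ll = 0.5 * 300 * (logdet - np.sum(R * K))
            expected = -2 * ll + E * np.log(300) + 4 * 0.5 * E * np.log(4)
            assert score == pytest.approx(expected, rel=1e-10)


class TestEstimateNetwork:
    def test_sixteen_nodes_enumerate_120_possible_edges(self, default_cohort):
        corr = spearman_matrix(default_cohort.responses)
        net, _ = estimate_network(corr, communities=default_cohort.truth.communities)
        assert net.p == 16
        assert net.n_possible_edges == 120
        assert len(net.edge_list()) == 120

    def test_identity_correlation_selects_empty_graph(self):
        corr = CorrelationMatrix([f"v{i}" for i in range(5)], np.eye(5), n=100)
        net, _ = estimate_network(corr)
        assert net.n_edges == 0

    def test_edge_weights_shrink_monotonically_along_path(self):
        R = random_correlation(6, seed=7, strength=0.4)
        corr = CorrelationMatrix([f"v{i}" for i in range(6)], R, n=400)
        _, path = estimate_network(corr, n_lambdas=20)
        Ws = [np.abs(precision_to_partial(K)) for K in path.precisions]
        for a, b in zip(Ws, Ws[1:]):  # lambdas decrease along the path
            assert np.all(b >= a - 1e-6)

    def test_edge_count_nondecreasing_as_lambda_decreases(self):
        R = random_correlation(6, seed=8, strength=0.4)
        corr = CorrelationMatrix([f"v{i}" for i in range(6)], R, n=400)
        _, path = estimate_network(corr, n_lambdas=20)
        counts = path.edge_counts
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_permutation_equivariance(self):
        R = random_correlation(5, seed=9, strength=0.4)
        labels = [f"v{i}" for i in range(5)]
        corr = CorrelationMatrix(labels, R, n=300)
        net, _ = estimate_network(corr)
        perm = [3, 0, 4, 1, 2]
        corr_p = CorrelationMatrix(
            [labels[i] for i in perm], R[np.ix_(perm, perm)], n=300
        )
        net_p, _ = estimate_network(corr_p)
        assert np.allclose(net_p.W, net.W[np.ix_(perm, perm)], atol=1e-6)

    def test_larger_gamma_never_denser(self):
        R = random_correlation(8, seed=10, strength=0.4)
        corr = CorrelationMatrix([f"v{i}" for i in range(8)], R, n=200)
        net_lo, _ = estimate_network(corr, gamma=0.0)
        net_hi, _ = estimate_network(corr, gamma=1.0)
        assert net_hi.n_edges <= net_lo.n_edges

    def test_unpenalised_limit_recovers_analytic_partials(self):
        # p=3 Gaussian with known precision; large-n Pearson R, lambda -> 0
        K_true = np.array(
            [[1.5, -0.4, 0.0], [-0.4, 1.5, -0.3], [0.0, -0.3, 1.5]]
        )
        S = np.linalg.inv(K_true)
        d = np.sqrt(np.diag(S))
        R_pop = S / np.outer(d, d)
        rng = np.random.default_rng(12)
        X = rng.multivariate_normal(np.zeros(3), R_pop, size=50000)
        R_hat = np.corrcoef(X.T)
        np.fill_diagonal(R_hat, 1.0)
        W_true = precision_to_partial(np.linalg.inv(R_pop))
        W_hat = precision_to_partial(glasso_fit((R_hat + R_hat.T) / 2, 0.0))
        assert np.allclose(W_hat, W_true, atol=0.02)

    def test_sparse_gaussian_recovery_eight_nodes(self):
        # known sparse 8-node GGM, continuous Gaussian data at n=5000:
        # selected pattern should recover truth with high sensitivity and
        # few false edges
        rng = np.random.default_rng(21)
        p = 8
        K = np.eye(p)
        edges = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7), (0, 4)]
        for i, j in edges:
            K[i, j] = K[j, i] = -0.35
        np.fill_diagonal(K, 1.1 * np.abs(K - np.diag(np.diag(K))).sum(1) + 1.0)
        S = np.linalg.inv(K)
        d = np.sqrt(np.diag(S))
        R_pop = S / np.outer(d, d)
        X = rng.multivariate_normal(np.zeros(p), R_pop, size=5000)
        R_hat = np.corrcoef(X.T)
        np.fill_diagonal(R_hat, 1.0)
        corr = CorrelationMatrix(
            [f"v{i}" for i in range(p)], (R_hat + R_hat.T) / 2, n=5000
        )
        net, _ = estimate_network(corr)
        W_true = precision_to_partial(np.linalg.inv(R_pop))
        iu = np.triu_indices(p, 1)
        truth_edge = np.abs(W_true[iu]) > 1e-8
        est_edge = np.abs(net.W[iu]) > 1e-8
        sensitivity = est_edge[truth_edge].mean()
        false_rate = est_edge[~truth_edge].mean()
        assert sensitivity >= 0.9
        assert false_rate <= 0.1
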