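"""Tests of Spearman-based EBIC graphical-lasso network estimation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import symnet as sn
from symnet.estimation import (CorrelationMatrix, EDGE_ZERO_TOL,
                               EstimationError, ebic, graphical_lasso_fit,
                               infer_communities, lambda_path,
                               precision_to_weights, repair_psd,
                               spearman_matrix)
from symnet.synthetic import NODE_NAMES


def corr(V, n=100, names=None):
    V = np.asarray(V, dtype=float)
    if names is None:
        names = tuple(f"V{i+1}" for i in range(V.shape[0]))
    return CorrelationMatrix(V, n=n, node_names=names)


def penalized_loglik(K, S, lam):
    """The objective glasso maximizes (diagonal unpenalized)."""
    off = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return np.linalg.slogdet(K)[1] - np.trace(S @ K) - lam * off


def brute_force_glasso(S, lam, p):
    """Independent numerical maximizer over the free parameters of K.

    Maximizes the penalized log-likelihood directly with L-BFGS on the
    p*(p+1)/2 free entries, smoothing |x| as sqrt(x^2 + eps) and driving
    eps -> 0 by warm-started continuation; the returned objective is the
    exact (non-smoothed) one.
    """
    iu = np.triu_indices(p)
    off_mask = iu[0] != iu[1]

    def unpack(theta):
        K = np.zeros((p, p))
        K[iu] = theta
        return K + K.T - np.diag(np.diag(K))

    theta = np.linalg.inv(S)[iu]
    for eps in (1e-6, 1e-10, 1e-14):
        def neg_smooth(theta):
            K = unpack(theta)
            if np.linalg.eigvalsh(K)[0] <= 1e-10:
                return 1e10
            pen = 2 * np.sqrt(theta[off_mask] ** 2 + eps).sum()
            return -(np.linalg.slogdet(K)[1] - np.trace(S @ K)) + lam * pen
        theta = minimize(neg_smooth, theta, method="L-BFGS-B",
                         options={"maxiter": 20000, "ftol": 1e-16,
                                  "gtol": 1e-12}).x
    K = unpack(theta)
    return K, penalized_loglik(K, S, lam)


class TestSpearmanMatrix:
    def test_perfectly_concordant_and_discordant(self):
        t = pd.DataFrame({"a": [0, 1, 2, 3], "b": [1, 2, 4, 9],
                          "c": [9, 4, 2, 1]})
        R = spearman_matrix(t).values
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks of x=(0,0,1) are (1.5,1.5,3); of y=(0,1,1) are (1,2.5,2.5);
        # their Pearson correlation is 0.5
        t = pd.DataFrame({"x": [0, 0, 1], "y": [0, 1, 1]})
        assert spearman_matrix(t).values[0, 1] == pytest.approx(0.5)

    def test_constant_column_named_in_error(self):
        t = pd.DataFrame({"x": [1, 1, 1], "y": [0, 1, 2]})
        with pytest.raises(ValueError, match="'x'"):
            spearman_matrix(t)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 4, size=(5000, 4)),
                         columns=list("abcd"))
        off = spearman_matrix(t).values[np.triu_indices(4, k=1)]
        assert np.abs(off).max() < 0.05

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"a": [0, 1], "b": [1, 0]}))


class TestRepairPSD:
    def test_identity_unchanged(self):
        c = corr(np.eye(4))
        assert repair_psd(c) is c

    def test_valid_correlation_unchanged(self):
        V = np.array([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]])
        c = corr(V)
        assert repair_psd(c) is c

    def test_indefinite_input_repaired(self):
        V = np.array([[1, 0.9, 0.9], [0.9, 1, -0.9], [0.9, -0.9, 1]])
        assert np.linalg.eigvalsh(V)[0] < 0  # genuinely indefinite
        out = repair_psd(corr(V))
        assert out.min_eigenvalue() >= 0
        assert np.allclose(np.diag(out.values), 1.0)
        assert np.allclose(out.values, out.values.T)


class TestLambdaPath:
    def test_log_spacing_by_hand(self):
        V = np.array([[1, 0.5], [0.5, 1]])
        path = lambda_path(corr(V), n_points=3, min_ratio=0.01)
        assert np.allclose(path, [0.5, 0.05, 0.005])

    def test_endpoints(self):
        V = np.array([[1, 0.3, 0.1], [0.3, 1, 0.2], [0.1, 0.2, 1]])
        path = lambda_path(corr(V), n_points=20, min_ratio=0.05)
        assert path[0] == pytest.approx(0.3)
        assert path[-1] == pytest.approx(0.3 * 0.05)
        assert np.all(np.diff(path) < 0)

    def test_identity_degenerate_path(self):
        with pytest.warns(UserWarning, match="degenerate"):
            path = lambda_path(corr(np.eye(3)))
        assert list(path) == [0.0]


class TestGraphicalLasso:
    def test_identity_input_identity_output(self):
        for lam in (0.0, 0.1, 0.9):
            K = graphical_lasso_fit(corr(np.eye(3)), lam)
            assert np.allclose(K, np.eye(3), atol=1e-8)

    def test_zero_penalty_inverts(self):
        S = np.array([[1, 0.6], [0.6, 1]])
        K = graphical_lasso_fit(corr(S), 0.0)
        assert np.allclose(K, np.linalg.inv(S))
        assert precision_to_weights(K)[0, 1] == pytest.approx(0.6)

    @pytest.mark.parametrize("lam", [0.05, 0.2])
    def test_matches_brute_force_maximizer_3x3(self, lam):
        S = np.array([[1, 0.5, 0.25], [0.5, 1, 0.35], [0.25, 0.35, 1]])
        K = graphical_lasso_fit(corr(S), lam)
        _, obj_oracle = brute_force_glasso(S, lam, 3)
        obj_fit = penalized_loglik(K, S, lam)
        assert obj_fit == pytest.approx(obj_oracle, abs=1e-6)

    def test_penalty_above_max_correlation_gives_empty_network(self):
        S = np.array([[1, 0.5, 0.25], [0.5, 1, 0.35], [0.25, 0.35, 1]])
        K = graphical_lasso_fit(corr(S), 0.5)
        off = K[np.triu_indices(3, k=1)]
        assert np.abs(off).max() < 1e-6
        # oracle agrees that the diagonal solution is optimal
        _, obj_oracle = brute_force_glasso(S, 0.5, 3)
        assert penalized_loglik(K, S, 0.5) == pytest.approx(obj_oracle,
                                                            abs=1e-6)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso_fit(corr(np.eye(2)), -0.1)


class TestPrecisionToWeights:
    def test_identity_and_2x2(self):
        assert np.all(precision_to_weights(np.eye(3)) == 0)
        K = np.array([[1, -0.5], [-0.5, 1]])
        assert precision_to_weights(K)[0, 1] == pytest.approx(0.5)

    def test_residual_regression_oracle_3_nodes(self):
        # w_ij must equal the correlation of the residuals of i and j after
        # regressing each on the remaining node, computed from Sigma = K^-1
        K = np.array([[1.2, -0.3, -0.1], [-0.3, 1.0, -0.25],
                      [-0.1, -0.25, 1.4]])
        Sig = np.linalg.inv(K)
        W = precision_to_weights(K)
        for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
            # residual covariance of (i, j) given k via Schur complement
            cii = Sig[i, i] - Sig[i, k] ** 2 / Sig[k, k]
            cjj = Sig[j, j] - Sig[j, k] ** 2 / Sig[k, k]
            cij = Sig[i, j] - Sig[i, k] * Sig[j, k] / Sig[k, k]
            assert W[i, j] == pytest.approx(cij / np.sqrt(cii * cjj),
                                            abs=1e-12)


class TestEBIC:
    def test_hand_evaluated_identity_case(self):
        # -2*(n/2)*(logdet I - tr(I)) = n * p = 300; no edge penalty
        val = ebic(np.eye(3), np.eye(3), n=100, gamma=0.5)
        assert val == pytest.approx(300.0)

    def test_gamma_irrelevant_for_diagonal_precision(self):
        S = np.array([[1, 0.2], [0.2, 1]])
        K = np.diag([1.1, 0.9])
        assert ebic(K, S, 50, gamma=0.0) == ebic(K, S, 50, gamma=5.0)

    def test_one_extra_edge_costs_logn_plus_penalty(self):
        n, p, gamma = 200, 4, 0.5
        K0 = np.eye(p)
        K1 = K0.copy()
        K1[0, 1] = K1[1, 0] = 1e-7  # negligible likelihood change
        delta = ebic(K1, np.eye(p), n, gamma) - ebic(K0, np.eye(p), n, gamma)
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(p),
                                      abs=1e-4)


class TestSelectNetwork:
    def test_empty_true_network_yields_near_empty_estimate(self):
        thr = sn.default_thresholds()
        tab = sn.sample_ordinal(np.eye(17), thr, n=2000, seed=21)
        model = sn.select_network(tab[list(NODE_NAMES)])
        assert model.edge_count <= 2
        assert np.abs(model.weights).max() < 0.05

    def test_selected_ebic_is_path_minimum_and_sparsity_monotone(
            self, study_table):
        model = sn.select_network(study_table[list(NODE_NAMES)],
                                  n_points=25, min_ratio=0.05)
        ebics = [e for _, e, _ in model.path]
        assert model.ebic_value == pytest.approx(min(ebics))
        counts = [c for _, _, c in model.path]  # path is decreasing in lambda
        assert counts[0] <= counts[-1]
        assert np.abs(model.weights).max() < 1
        assert np.allclose(np.diag(model.weights), 0)
        assert np.allclose(model.weights, model.weights.T)

    def test_zero_penalty_limit_equals_unregularized_partials(
            self, study_table):
        c = spearman_matrix(study_table[list(NODE_NAMES)])
        W0 = precision_to_weights(graphical_lasso_fit(c, 0.0))
        assert np.allclose(W0, sn.partial_correlations(c.values), atol=1e-10)

    def test_small_sample_warns(self, small_net, small_thr):
        tab = sn.sample_ordinal(sn.true_covariance(small_net), small_thr,
                                n=40, seed=3)
        with pytest.warns(UserWarning, match="unstable"):
            sn.select_network(tab[list(small_net.node_names)],
                              n_points=10, min_ratio=0.2)

    def test_communities_inferred_from_names(self):
        comm = infer_communities(("CESD1", "GAD2"))
        assert comm == ("depression", "anxiety")
        with pytest.raises(ValueError):
            infer_communities(("PHQ1",))
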