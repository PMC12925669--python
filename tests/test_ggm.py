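import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import graphical_lasso as sklearn_glasso

from speechnet.errors import SpeechNetError
from speechnet.ggm import (NetworkModel, ebic_score,
                           ebicglasso_select, glasso_fit,
                           pearson_correlation, precision_to_partial,
                           zscore_columns)
from speechnet.synthetic import planted_precision, sample_mvn_from_precision


class TestZscore:
    def test_basic_column(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1, 0, 1])

    def test_idempotent(self, rng):
        X = rng.standard_normal((40, 3))
        once = zscore_columns(X)
        assert np.allclose(zscore_columns(once), once, atol=1e-12)

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(SpeechNetError, match="b"):
            zscore_columns(df)

    def test_unit_sample_sd(self, rng):
        Z = zscore_columns(rng.standard_normal((25, 4)) * 7 + 3)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)


class TestPearsonCorrelation:
    def test_duplicated_column(self, rng):
        x = rng.standard_normal(30)
        ci = pearson_correlation(np.column_stack([x, x, rng.standard_normal(30)]))
        assert ci.S[0, 1] == pytest.approx(1.0)

    def test_negated_column(self, rng):
        x = rng.standard_normal(30)
        ci = pearson_correlation(np.column_stack([x, -x]))
        assert ci.S[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10_000, 5))
        ci = pearson_correlation(X)
        off = ci.S[np.triu_indices(5, k=1)]
        assert np.all(np.abs(off) < 0.03)

    def test_listwise_drops_incomplete_rows(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)))
        X.iloc[0, 0] = np.nan
        ci = pearson_correlation(X, missing_policy="listwise")
        assert ci.n == 19

    def test_small_n_warns(self, rng):
        X = rng.standard_normal((4, 6))
        with pytest.warns(UserWarning, match="sample size"):
            pearson_correlation(X)


def p2_soft_threshold(s, lam):
    """Closed-form glasso solution at p=2 with unpenalized diagonal:
    the off-diagonal covariance soft-thresholds, and the implied partial
    correlation equals that soft-thresholded value."""
    return np.sign(s) * max(abs(s) - lam, 0.0)


class TestGlassoFit:
    def test_full_shrinkage_gives_diagonal(self, rng):
        Theta0, _ = planted_precision(5, "chain", 0.3)
        S = np.linalg.inv(Theta0)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        lam_max = np.abs(S - np.eye(5)).max()
        Theta = glasso_fit(S, lam_max + 0.01)
        assert np.count_nonzero(Theta - np.diag(np.diag(Theta))) == 0

    def test_p2_example(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        Theta = glasso_fit(S, 0.1)
        W = precision_to_partial(Theta)
        assert W[0, 1] == pytest.approx(0.5, abs=1e-6)

    def test_lambda_zero_inverts(self, rng):
        X = rng.standard_normal((200, 4))
        S = np.corrcoef(X, rowvar=False)
        Theta = glasso_fit(S, 0.0, tol=1e-7)
        assert np.allclose(Theta, np.linalg.inv(S), atol=1e-5)

    def test_p2_closed_form_grid(self):
        # exhaustive small-instance equivalence with the soft-threshold oracle
        for s in (-0.8, -0.3, 0.2, 0.6, 0.9):
            S = np.array([[1.0, s], [s, 1.0]])
            for lam in np.linspace(0.0, 1.0, 21):
                W = precision_to_partial(glasso_fit(S, lam, tol=1e-6))
                assert W[0, 1] == pytest.approx(p2_soft_threshold(s, lam),
                                                abs=1e-6)

    @pytest.mark.parametrize("lam", [0.02, 0.05, 0.1, 0.2])
    def test_matches_sklearn_oracle(self, rng, lam):
        X = rng.standard_normal((80, 6))
        S = np.corrcoef(X, rowvar=False)
        Theta = glasso_fit(S, lam, tol=1e-8)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = sklearn_glasso(S, alpha=lam, tol=1e-10, max_iter=5000)
        # both solvers run to tight change-based tolerances; residual
        # disagreement concentrates on barely-active edges
        assert np.abs(Theta - prec).max() < 5e-4

    def test_negative_penalty_rejected(self):
        with pytest.raises(SpeechNetError):
            glasso_fit(np.eye(3), -0.1)


class TestEbicScore:
    def test_identity_evaluation(self):
        # logdet = 0, trace = 3, L = -15, E = 0 -> EBIC = 30
        assert ebic_score(np.eye(3), np.eye(3), n=10, gamma=0.5) == pytest.approx(30.0)

    def test_gamma_zero_is_bic(self, rng):
        Theta0, _ = planted_precision(4, "chain", 0.3)
        S = np.eye(4)
        E = 3  # chain edges
        diff = (ebic_score(Theta0, S, 50, 0.5)
                - ebic_score(Theta0, S, 50, 0.0))
        assert diff == pytest.approx(4 * E * 0.5 * np.log(4))

    def test_denser_model_penalized(self):
        S = np.eye(4)
        sparse = np.eye(4)
        dense, _ = planted_precision(4, "chain", 1e-9)
        # likelihoods agree to ~1e-18; the penalty difference dominates
        assert ebic_score(dense, S, 100, 0.5) > ebic_score(sparse, S, 100, 0.5)

    def test_non_pd_rejected(self):
        with pytest.raises(SpeechNetError, match="positive definite"):
            ebic_score(-np.eye(3), np.eye(3), 10, 0.5)


class TestPrecisionToPartial:
    def test_diagonal_gives_empty_network(self):
        W = precision_to_partial(np.diag([1.0, 2.0, 3.0]))
        assert np.all(W == 0)

    def test_sign_flip(self, rng):
        Theta, _ = planted_precision(5, "chain", 0.3)
        W = precision_to_partial(Theta)
        off = ~np.eye(5, dtype=bool)
        assert np.all(np.sign(W[off]) == -np.sign(Theta[off]))


class TestEbicglassoSelect:
    def test_null_data_nearly_empty(self):
        # independent normals: the selected model has at most one spurious
        # edge in at least 95% of seeded runs
        good = 0
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((2000, 10))
            S = np.corrcoef(X, rowvar=False)
            net = ebicglasso_select(S, n=2000, gamma=0.5)
            n_edges = np.count_nonzero(np.triu(net.weights, k=1))
            good += n_edges <= 1
        assert good >= 19

    def test_chain_recovery_with_signs(self):
        Theta, edges = planted_precision(10, "chain", 0.3)
        X = sample_mvn_from_precision(Theta, 2000, seed=0)
        net = ebicglasso_select(np.corrcoef(X, rowvar=False), n=2000)
        for i, j in edges:
            assert net.weights[i, j] > 0  # planted partials are +0.3

    def test_gamma_monotone_edge_count(self):
        Theta, _ = planted_precision(8, "chain", 0.35)
        X = sample_mvn_from_precision(Theta, 300, seed=3)
        S = np.corrcoef(X, rowvar=False)
        counts = []
        for gamma in (0.0, 0.25, 0.5, 1.0):
            net = ebicglasso_select(S, n=300, gamma=gamma)
            counts.append(np.count_nonzero(np.triu(net.weights, k=1)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_relabeling_equivariance(self, rng):
        Theta, _ = planted_precision(6, "chain", 0.3)
        X = sample_mvn_from_precision(Theta, 500, seed=5)
        S = np.corrcoef(X, rowvar=False)
        net = ebicglasso_select(S, n=500)
        perm = rng.permutation(6)
        net_p = ebicglasso_select(S[np.ix_(perm, perm)], n=500)
        assert np.allclose(net_p.weights, net.weights[np.ix_(perm, perm)],
                           atol=1e-8)

    def test_model_invariants(self, rng):
        Theta, _ = planted_precision(7, "hub", 0.25)
        X = sample_mvn_from_precision(Theta, 400, seed=9)
        net = ebicglasso_select(np.corrcoef(X, rowvar=False), n=400)
        W = net.weights
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert np.all(np.abs(W) < 1)
        assert net.lambda_selected in net.lambda_grid
        assert len(net.ebic_path) == len(net.lambda_grid)


class TestNetworkModel:
    def test_asymmetric_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.5
        with pytest.raises(SpeechNetError, match="symmetric"):
            NetworkModel(W, ["a", "b", "c"], {}, n=10, gamma=0.5)

    def test_json_round_trip(self, tmp_path, rng):
        Theta, _ = planted_precision(5, "chain", 0.3)
        X = sample_mvn_from_precision(Theta, 300, seed=2)
        net = ebicglasso_select(np.corrcoef(X, rowvar=False), n=300)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = NetworkModel.from_json(path)
        assert np.allclose(back.weights, net.weights)
        assert back.nodes == net.nodes
        assert back.lambda_selected == net.lambda_selected
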