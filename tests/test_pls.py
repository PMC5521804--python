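"""NIPALS PLS1 core: oracle equivalences, VIP identity, CV, permutation,
post-transformation and PCA."""

import numpy as np
import pandas as pd
import pytest

import phytoplex as px
from phytoplex.errors import DegenerateDesignError, ParameterError
from phytoplex.pls import _fold_assignments


class TestFitPLS1:
    def test_exact_univariate_line(self):
        x = np.linspace(-2, 2, 12).reshape(-1, 1)
        y = 3.0 * x.ravel()
        m = px.fit_pls1(x, y, 1)
        assert m.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(m.predict(x), y, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(10, 30)), int(rng.integers(2, 8))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        m = px.fit_pls1(X, y, p)
        A = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(m.predict(X), A @ beta, atol=1e-8)

    def test_orthogonal_response_gives_null_model(self):
        # y orthogonal to every centered column -> b ~ 0, r2 ~ 0
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        y = y - y.mean()
        assert np.allclose((X - X.mean(0)).T @ y, 0)
        with pytest.warns(UserWarning):
            m = px.fit_pls1(X, y, 1)
        np.testing.assert_allclose(m.b, 0.0, atol=1e-8)
        assert m.r2 == pytest.approx(0.0, abs=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(25, 10))
        y = X[:, 0] + 0.5 * X[:, 3] + rng.normal(size=25) * 0.2
        m = px.fit_pls1(X, y, 4)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(DegenerateDesignError):
            px.fit_pls1(rng.normal(size=(10, 3)), np.ones(10), 1)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ParameterError):
            px.fit_pls1(rng.normal(size=(5, 3)), rng.normal(size=5), 5)


class TestVIP:
    def test_single_variable_vip_is_one(self):
        x = np.linspace(0, 1, 8).reshape(-1, 1)
        m = px.fit_pls1(x, 2 * x.ravel() + 0.1, 1)
        np.testing.assert_allclose(m.vip, [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_square_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=20) * 0.3
        m = px.fit_pls1(X, y, 3)
        assert (m.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_direct_formula_evaluation(self, rng):
        # independent evaluation of the VIP formula from W, T, q
        X = rng.normal(size=(15, 4))
        y = X[:, 0] * 2 + X[:, 1] + rng.normal(size=15) * 0.1
        m = px.fit_pls1(X, y, 2)
        p = 4
        ssy = np.array([m.q[a] ** 2 * (m.T[:, a] @ m.T[:, a]) for a in range(2)])
        expect = np.sqrt(
            p
            * sum(
                ssy[a] * (m.W[:, a] / np.linalg.norm(m.W[:, a])) ** 2
                for a in range(2)
            )
            / ssy.sum()
        )
        np.testing.assert_allclose(m.vip, expect, atol=1e-10)


class TestCrossValidation:
    def test_noiseless_linear_q2_near_one(self, rng):
        X = rng.normal(size=(70, 5))
        y = X @ np.array([1.0, 2, 0, 0, 1])
        q2, _ = px.q2_sdecv(X, y, 3, folds=7, seed=0)
        assert q2 >= 0.999

    def test_press_matches_hand_stepped_folds(self):
        # 8 samples, 2 folds with the same assignment the implementation
        # draws; per-fold models recomputed independently with sklearn
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=8) * 0.1
        seed = 11
        fold = _fold_assignments(8, 2, np.random.default_rng(seed))
        press = tss = 0.0
        for k in range(2):
            test = fold == k
            train = ~test
            sk = PLSRegression(n_components=2, scale=False).fit(
                X[train], y[train].reshape(-1, 1)
            )
            pred = sk.predict(X[test]).ravel()
            press += float(((y[test] - pred) ** 2).sum())
            tss += float(((y[test] - y[train].mean()) ** 2).sum())
        q2, sdecv = px.q2_sdecv(X, y, 2, folds=2, seed=seed)
        assert q2 == pytest.approx(1 - press / tss, abs=1e-8)
        assert sdecv == pytest.approx(np.sqrt(press / 8), abs=1e-8)

    def test_null_q2_negative_in_expectation(self):
        q2s = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 5))
            y = rng.normal(size=30)
            q2, _ = px.q2_sdecv(X, y, 2, folds=7, seed=seed)
            q2s.append(q2)
        assert np.mean(q2s) < 0

    def test_q2_never_exceeds_r2_on_same_data(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] + rng.normal(size=40) * 0.5
        m = px.fit_pls1(X, y, 2)
        q2, _ = px.q2_sdecv(X, y, 2, folds=7, seed=0)
        assert q2 <= m.r2 + 1e-8

    def test_folds_exceeding_samples_rejected(self, rng):
        with pytest.raises(ParameterError):
            px.q2_sdecv(rng.normal(size=(5, 2)), rng.normal(size=5), 1, folds=7)


class TestSelectByVIP:
    def test_planted_informative_variable_selected(self):
        rng = np.random.default_rng(0)
        n = 54
        X = rng.normal(size=(n, 21))
        y = 5.0 * X[:, 0] + rng.normal(size=n) * 0.5
        Xdf = pd.DataFrame(X, columns=[f"v{j}" for j in range(21)])
        res = px.select_by_vip(Xdf, y, seed=0)
        assert "v0" in res.selected
        full_vip = res.full_model.vip
        assert full_vip[0] > 1.0

    def test_exchangeable_pair_both_selected(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x})  # exactly exchangeable duplicates
        y = x + rng.normal(size=30) * 0.1
        res = px.select_by_vip(X, y, seed=1)
        assert set(res.selected) == {"a", "b"}

    def test_matches_brute_force_over_vip_ordered_subsets(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 6))
        y = 2 * X[:, 0] + X[:, 1] + rng.normal(size=24) * 0.8
        Xdf = pd.DataFrame(X, columns=[f"v{j}" for j in range(6)])
        res = px.select_by_vip(Xdf, y, seed=2)
        vip = res.full_model.vip
        order = np.argsort(-vip)
        best_q2, best_set = -np.inf, None
        for k in range(1, 7):  # all VIP-ordered prefixes, sparsest kept on ties
            cols = [Xdf.columns[j] for j in order[:k]]
            _, q2, _ = px.choose_components(Xdf[cols], y, seed=2)
            if q2 > best_q2 + 1e-12:
                best_q2, best_set = q2, set(cols)
        assert set(res.selected) == best_set
        assert res.model.q2 == pytest.approx(best_q2, abs=1e-10)

    def test_q2_path_maximum_is_returned_model(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 8)))
        y = X.iloc[:, 0] * 2 + rng.normal(size=30) * 0.5
        res = px.select_by_vip(X, y, seed=3)
        assert res.model.q2 == pytest.approx(max(q for _, q, _ in res.q2_path))


class TestPermutationTest:
    def test_informative_response_gets_minimum_p(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ np.array([2.0, 1, 0, 0, 0]) + rng.normal(size=40) * 0.1
        p = px.permutation_test(X, y, n_perm=49, seed=0, n_components=2)
        assert p == pytest.approx(1 / 50)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        p1 = px.permutation_test(X, y, n_perm=29, seed=4, n_components=2)
        p2 = px.permutation_test(X, y, n_perm=29, seed=4, n_components=2)
        assert p1 == p2


class TestPostTransform:
    def test_single_component_tp_proportional_to_t1(self, rng):
        X = rng.normal(size=(20, 4))
        y = X[:, 0] + rng.normal(size=20) * 0.2
        m = px.post_transform(px.fit_pls1(X, y, 1))
        c = np.corrcoef(m.tp, m.T[:, 0])[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)

    def test_tp_perfectly_correlated_with_fitted(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25) * 0.3
        m = px.fit_pls1(X, y, 3)
        mt = px.post_transform(m)
        c = np.corrcoef(mt.tp, m.predict(X))[0, 1]
        assert c == pytest.approx(1.0, abs=1e-8)

    def test_predictions_unchanged(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25) * 0.3
        m = px.fit_pls1(X, y, 3)
        before = m.predict(X)
        after = px.post_transform(m).predict(X)
        np.testing.assert_allclose(before, after, atol=1e-10)

    def test_remaining_components_orthogonal_to_tp(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25) * 0.3
        mt = px.post_transform(px.fit_pls1(X, y, 3))
        T_o = mt.T_orthogonal
        np.testing.assert_allclose(T_o.T @ mt.tp, 0.0, atol=1e-8)


class TestPCA:
    def test_rank_one_single_component(self):
        u = np.arange(1.0, 7)[:, None]
        v = np.array([[1.0, 2, 3]])
        with pytest.warns(UserWarning):
            _, _, explained = px.pca(u @ v, 3)
        assert explained[0] == pytest.approx(1.0)

    def test_fractions_monotone_and_bounded(self, rng):
        _, _, explained = px.pca(rng.normal(size=(12, 5)))
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1 + 1e-12

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(5, 4))
        scores, loadings, explained = px.pca(X, 3)
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(
            explained[:3], evals[:3] / evals.sum(), atol=1e-10
        )
        for j in range(3):  # loadings match up to sign
            dot = abs(loadings[:, j] @ evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)
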