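"""PCA and NIPALS PLS against independent oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression

from corehybrid import (PLSModel, adjusted_r2, fit_pls, max_components, pca,
                        select_n_components, vip)


def _random_problem(seed, n=20, p=6, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if signal:
        y = X @ rng.normal(size=p) + 0.2 * rng.normal(size=n)
    else:
        y = rng.normal(size=n)
    return X, y


class TestPCA:
    def test_single_varying_column_explains_everything(self):
        X = np.zeros((5, 3))
        X[:, 1] = [1.0, 2.0, 3.0, 4.0, 5.0]
        result = pca(X)
        assert result.explained_variance[0] == pytest.approx(1.0)

    def test_scores_match_eigendecomposition_oracle(self):
        X = np.array([[2.0, 0.0, 1.0], [0.0, 1.0, 3.0],
                      [1.0, 5.0, 2.0], [4.0, 2.0, 0.0]])
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        oracle = Xc @ evecs[:, order]
        result = pca(X)
        for j in range(3):
            assert (np.allclose(result.scores[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(result.scores[:, j], -oracle[:, j], atol=1e-8))

    def test_duplicating_samples_leaves_loadings_unchanged(self):
        X, _ = _random_problem(0, n=8, p=4)
        doubled = np.vstack([X, X])
        assert np.allclose(pca(X).loadings, pca(doubled).loadings, atol=1e-8)

    def test_loading_columns_orthonormal_and_variance_sorted(self):
        X, _ = _random_problem(1, n=15, p=5)
        result = pca(X)
        gram = result.loadings.T @ result.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        assert (np.diff(result.explained_variance) <= 1e-12).all()
        assert result.explained_variance.sum() <= 1 + 1e-12

    def test_sign_convention_largest_loading_positive(self):
        X, _ = _random_problem(2, n=12, p=4)
        loadings = pca(X).loadings
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            pca(np.ones((1, 3)))


class TestFitPLS:
    def test_single_predictor_collapses_to_simple_regression(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = 2.5 * x + 1.0 + 0.1 * rng.normal(size=12)
        model = fit_pls(x[:, None], y, 1)
        slope, intercept = np.polyfit(x, y, 1)
        assert model.coef[0] == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)

    def test_full_component_fit_equals_ols_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=10)
        model = fit_pls(X, y, 3)
        Xa = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
        assert np.allclose(model.coef, beta[1:], atol=1e-6)
        assert model.intercept == pytest.approx(beta[0], abs=1e-6)

    def test_scores_orthogonal_and_forms_agree(self):
        X, y = _random_problem(5)
        model = fit_pls(X, y, 4)
        T = model.x_scores
        off = T.T @ T - np.diag(np.einsum("ij,ij->j", T, T))
        assert np.abs(off).max() < 1e-8 * np.abs(T).max() ** 2
        assert np.allclose(model.predict(X), model.predict_factors(X), atol=1e-8)

    def test_uninformative_response_gives_near_zero_r2(self):
        X, y = _random_problem(6, n=200, p=5, signal=False)
        assert fit_pls(X, y, 1).r2 < 0.05

    def test_requesting_too_many_components_reports_maximum(self):
        X, y = _random_problem(7, n=5, p=10)
        with pytest.raises(ValueError, match="4"):
            fit_pls(X, y, 8)

    def test_rank_deficient_extraction_cap_reported(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(12, 2))
        X = base @ rng.normal(size=(2, 6))      # rank 2
        y = X @ rng.normal(size=6)
        assert max_components(X, y) == 2
        with pytest.raises(ValueError, match="2 latent factors"):
            fit_pls(X, y, 5)

    def test_matches_sklearn_nipals_coefficients(self):
        X, y = _random_problem(9, n=25, p=8)
        model = fit_pls(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(model.coef, ref.coef_.ravel(), atol=1e-8)
        assert np.allclose(model.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_prediction_invariant_to_predictor_reordering(self):
        X, y = _random_problem(10)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        direct = fit_pls(X, y, 3).predict(X)
        shuffled = fit_pls(X[:, perm], y, 3).predict(X[:, perm])
        assert np.allclose(direct, shuffled, atol=1e-8)

    def test_serialisation_round_trip(self):
        X, y = _random_problem(11)
        model = fit_pls(X, y, 2, feature_names=[f"m{i}" for i in range(6)])
        clone = PLSModel.from_dict(model.to_dict())
        assert np.allclose(clone.predict(X), model.predict(X))
        assert clone.feature_names == model.feature_names


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 50, 5) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert adjusted_r2(0.5, 101, 5) == pytest.approx(1 - 0.5 * 100 / 95)

    def test_zero_factors_returns_r2(self):
        assert adjusted_r2(0.37, 20, 0) == pytest.approx(0.37)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 6, 5)


class TestSelectNComponents:
    def test_rank_two_signal_peaks_at_two(self):
        rng = np.random.default_rng(12)
        latent = rng.normal(size=(60, 2))
        X = latent @ rng.normal(size=(2, 8))        # exactly rank 2
        y = latent @ np.array([1.0, -1.5])
        a_star, path = select_n_components(X, y, 6)
        assert a_star == 2
        assert np.argmax(path) == 1

    def test_constant_response_falls_back_to_one_component(self):
        X, _ = _random_problem(13)
        a_star, path = select_n_components(X, np.full(20, 3.0), 5)
        assert a_star == 1
        assert np.allclose(path, 0.0)

    def test_single_candidate(self):
        X, y = _random_problem(14)
        assert select_n_components(X, y, 1)[0] == 1

    def test_training_r2_non_decreasing_along_path(self):
        X, y = _random_problem(15, n=30, p=6)
        r2s = [fit_pls(X, y, a).r2 for a in range(1, 6)]
        assert (np.diff(r2s) >= -1e-12).all()


class TestVIP:
    def test_single_predictor_vip_is_exactly_one(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=15)
        model = fit_pls(x[:, None], 2 * x + rng.normal(size=15), 1)
        assert model.vip[0] == 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        p = int(rng.integers(2, 12))
        a = int(rng.integers(1, min(n - 1, p) + 1))
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        model = fit_pls(X, y, a)
        assert np.mean(model.vip ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_component1_vip_on_constructed_weights(self):
        """Two identical informative columns and four orthogonal noise
        columns force w1 = (1,1,0,0,0,0)/sqrt(2), hence VIP =
        (sqrt(3), sqrt(3), 0, 0, 0, 0)."""
        rng = np.random.default_rng(17)
        tc = rng.normal(size=40)
        tc -= tc.mean()
        others = rng.normal(size=(40, 4))
        others -= others.mean(axis=0)
        # project the informative direction out of the centred noise columns
        others -= np.outer(tc, tc @ others) / (tc @ tc)
        X = np.column_stack([tc, tc, others])
        model = fit_pls(X, tc, 1)
        expected = np.array([np.sqrt(3), np.sqrt(3), 0, 0, 0, 0])
        assert np.allclose(model.vip_for(1), expected, atol=1e-8)

    def test_more_components_than_fitted_rejected(self):
        X, y = _random_problem(18)
        model = fit_pls(X, y, 2)
        with pytest.raises(ValueError):
            vip(model, 3)
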