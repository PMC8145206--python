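"""PLS1 engine: OLS limits, invariants, VIP/BETA scores, fit metrics."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from mirbw import (
    PlsModel,
    beta_scores,
    fit_pls,
    predict,
    predict_path,
    r2,
    rmse,
    vip_scores,
)


def _random_instance(seed, n=30, p=5, informative=2, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:informative] = rng.uniform(1, 2, informative)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestOlsLimits:
    def test_single_predictor_equals_least_squares_line(self):
        X, y = _random_instance(0, n=25, p=1, informative=1)
        model = fit_pls(X, y, 1)
        slope, intercept = np.polyfit(X[:, 0], y, 1)
        np.testing.assert_allclose(
            predict(model, X), slope * X[:, 0] + intercept, atol=1e-10
        )

    def test_full_rank_coefficients_match_normal_equations(self):
        X, y = _random_instance(1, n=20, p=4, informative=4)
        model = fit_pls(X, y, 4)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        np.testing.assert_allclose(model.coefficients, b_ols, atol=1e-8)
        fitted_ols = y.mean() + Xc @ b_ols
        np.testing.assert_allclose(predict(model, X), fitted_ols, atol=1e-8)

    def test_centered_row_predicts_training_mean(self):
        X, y = _random_instance(2, n=20, p=4)
        model = fit_pls(X, y, 2)
        yh = predict(model, X.mean(axis=0, keepdims=True))
        assert yh[0] == pytest.approx(y.mean())


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weights_unit_norm_scores_orthogonal(self, seed):
        X, y = _random_instance(seed, n=40, p=8, informative=3)
        model = fit_pls(X, y, 5)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-10)
        T = model.scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.all(np.abs(off) < 1e-8 * np.outer(norms, norms))

    def test_training_rmse_monotone_in_components(self):
        X, y = _random_instance(3, n=50, p=10, informative=4)
        model = fit_pls(X, y, 8)
        errs = [rmse(y, p) for p in predict_path(model, X)]
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_agrees_with_sklearn_pls(self):
        # independent implementation cross-check on the same standardized data
        X, y = _random_instance(4, n=60, p=12, informative=5)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        for A in (1, 3, 5):
            ours = predict(fit_pls(Xs, y, A), Xs)
            ref = PLSRegression(n_components=A, scale=False).fit(Xs, y).predict(Xs).ravel()
            np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_rank_deficient_stops_early_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0]])  # duplicate column: rank 3
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_pls(X, y, 4)
        assert model.n_components < 4


class TestVip:
    @pytest.mark.parametrize("seed,p,A", [(0, 5, 2), (1, 12, 4), (2, 30, 6)])
    def test_sum_of_squares_equals_p(self, seed, p, A):
        X, y = _random_instance(seed, n=60, p=p, informative=3)
        scores = vip_scores(fit_pls(X, y, A)).scores
        assert np.sum(scores**2) == pytest.approx(p, abs=1e-8)

    def test_single_feature_vip_is_one(self):
        X, y = _random_instance(3, n=25, p=1, informative=1)
        assert vip_scores(fit_pls(X, y, 1)).scores[0] == pytest.approx(1.0)

    def test_matches_literal_formula(self):
        X, y = _random_instance(6, n=30, p=5, informative=2)
        model = fit_pls(X, y, 2)
        # independent transcription from W, q, and score norms
        ssy = model.q**2 * model.score_norms
        expected = np.sqrt(
            len(model.feature_ids)
            * (model.W**2 @ ssy)
            / ssy.sum()
        )
        ranking = vip_scores(model)
        got = {f: s for f, s in zip(ranking.feature_ids, ranking.scores)}
        for j, fid in enumerate(model.feature_ids):
            assert got[fid] == pytest.approx(expected[j], abs=1e-10)

    def test_descending_with_index_tiebreak(self):
        X, y = _random_instance(7, n=40, p=6)
        ranking = vip_scores(fit_pls(X, y, 3))
        assert all(a >= b for a, b in zip(ranking.scores, ranking.scores[1:]))


class TestBeta:
    def test_pure_noise_feature_ranks_last_most_seeds(self):
        last = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = _random_instance(seed, n=80, p=4, informative=4, noise=0.2)
            X = np.column_stack([X, rng.normal(size=80)])
            ranking = beta_scores(fit_pls(X, y, 4))
            last += ranking.feature_ids[-1] == "x4"
        assert last >= 18  # >= 90% of seeds

    def test_duplicated_informative_feature_splits_weight(self):
        X, y = _random_instance(8, n=60, p=3, informative=2, noise=0.2)
        X = np.column_stack([X, X[:, 0]])
        model = fit_pls(X, y, 3)
        ranking = beta_scores(model)
        scores = {f: s for f, s in zip(ranking.feature_ids, ranking.scores)}
        assert scores["x0"] > 0 and scores["x3"] > 0


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_hand_computed_rmse(self):
        assert rmse(np.array([3.0, 4.0]), np.zeros(2)) == pytest.approx(
            np.sqrt(12.5)
        )

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([2.0, 4.0, 6.0, 8.0])
        assert r2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_constant_y_r2_undefined(self):
        with pytest.raises(ValueError):
            r2(np.ones(5), np.ones(5))


class TestCvNullBehaviour:
    def test_independent_response_gives_no_cv_skill(self):
        # cross-validated R^2 should hover at or below zero skill
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 10))
            y = rng.normal(size=60)
            half = 30
            model = fit_pls(X[:half], y[:half], 3)
            yh = predict(model, X[half:])
            r2s.append(r2(y[half:], yh))
        assert np.mean(r2s) <= 0.05


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self):
        X, y = _random_instance(9, n=40, p=6)
        model = fit_pls(X, y, 3, feature_ids=[f"f{j}" for j in range(6)])
        back = PlsModel.from_json(model.to_json())
        np.testing.assert_allclose(predict(back, X), predict(model, X), atol=1e-12)
        assert back.feature_ids == model.feature_ids
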