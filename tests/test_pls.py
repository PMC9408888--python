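"""NIPALS PLS1: autoscaling, fit, VIP, LOOCV and permutation testing,
each checked against an independently coded oracle."""

import numpy as np
import pandas as pd
import pytest

from steatomir import ValidationError
from steatomir.pls import (
    PLS1Model,
    autoscale,
    loocv_rmsecv,
    permutation_test,
    pls1_fit,
    select_components,
    vip_scores,
)


def _ols_predictions(X, y):
    """Oracle: intercept-including normal-equations least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return A @ beta


class TestAutoscale:
    def test_symmetric_column(self):
        scaled, mean, sd = autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(scaled[:, 0], [-1, 0, 1], atol=1e-12)
        assert mean[0] == 2.0 and sd[0] == 1.0

    def test_idempotent_and_round_trip(self, rng):
        X = rng.normal(size=(6, 3)) * 4 + 7
        scaled, mean, sd = autoscale(X)
        assert np.all(np.abs(scaled.mean(0)) < 1e-10)
        assert np.all(np.abs(scaled.std(0, ddof=1) - 1) < 1e-10)
        rescaled, m2, s2 = autoscale(scaled)
        np.testing.assert_allclose(rescaled, scaled, atol=1e-10)
        np.testing.assert_allclose(scaled * sd + mean, X, atol=1e-10)

    def test_constant_column_names_feature(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValidationError, match="hsa-miR-7-5p"):
            autoscale(X, feature_names=["hsa-miR-6-5p", "hsa-miR-7-5p"])


class TestPLS1Fit:
    def test_single_feature_equals_univariate_least_squares(self, rng):
        x = rng.normal(size=10)
        y = 2 * x + rng.normal(size=10) * 0.3
        xs, _, _ = autoscale(x[:, None].copy())
        ys, _, _ = autoscale(y)
        fit = pls1_fit(xs, ys, 1)
        slope = float(xs[:, 0] @ ys / (xs[:, 0] @ xs[:, 0]))  # closed-form oracle
        assert fit.coef()[0] == pytest.approx(slope, abs=1e-12)

    def test_full_components_equal_ols_on_tall_data(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20)
        res = PLS1Model(y, X).fit(n_components=5)
        np.testing.assert_allclose(res.fittedvalues, _ols_predictions(X, y), atol=1e-8)

    def test_y_orthogonal_to_features_gives_zero_coefficients(self):
        Xs = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        ys = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to both columns
        fit = pls1_fit(Xs, ys, 1)
        np.testing.assert_allclose(fit.coef(), 0.0, atol=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        Xs, _, _ = autoscale(X)
        ys, _, _ = autoscale(y)
        T = pls1_fit(Xs, ys, 5).T
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_component_count_validated(self, rng):
        Xs, _, _ = autoscale(rng.normal(size=(5, 3)))
        ys, _, _ = autoscale(rng.normal(size=5))
        with pytest.raises(ValidationError):
            pls1_fit(Xs, ys, 5)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(18, 7)) * 3 + 1
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(size=18)
        res = PLS1Model(y, X).fit(n_components=3)
        ref = sklearn.PLSRegression(n_components=3, scale=True).fit(X, y[:, None])
        np.testing.assert_allclose(
            res.fittedvalues, ref.predict(X)[:, 0], atol=1e-8
        )


class TestVIP:
    def test_single_feature_vip_is_one(self, rng):
        x = rng.normal(size=8)
        y = x + rng.normal(size=8) * 0.1
        xs, _, _ = autoscale(x[:, None].copy())
        ys, _, _ = autoscale(y)
        np.testing.assert_allclose(vip_scores(pls1_fit(xs, ys, 1)), [1.0], atol=1e-12)

    def test_equal_weights_give_unit_vips(self, rng):
        t = rng.normal(size=12)
        X = np.tile(t[:, None], (1, 4)) + rng.normal(size=(12, 4)) * 1e-9
        y = t
        Xs, _, _ = autoscale(X)
        ys, _, _ = autoscale(y)
        np.testing.assert_allclose(vip_scores(pls1_fit(Xs, ys, 1)), 1.0, atol=1e-3)

    def test_sum_of_squares_equals_feature_count(self, rng):
        for _ in range(20):
            n, p = 12, 10
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            Xs, _, _ = autoscale(X)
            ys, _, _ = autoscale(y)
            a = int(rng.integers(1, 6))
            vip = vip_scores(pls1_fit(Xs, ys, a))
            assert np.sum(vip**2) == pytest.approx(p, abs=1e-8)


class TestLOOCV:
    def test_hand_computed_four_sample_fixture(self):
        """Fold-by-fold manual enumeration of univariate LOOCV."""
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 3.0, 5.0, 7.0])
        preds = np.empty(4)
        for i in range(4):  # oracle: explicit scaling + closed-form slope per fold
            tr = np.arange(4) != i
            xm, xs = x[tr].mean(), x[tr].std(ddof=1)
            ym, ys = y[tr].mean(), y[tr].std(ddof=1)
            xt, yt = (x[tr] - xm) / xs, (y[tr] - ym) / ys
            slope = (xt @ yt) / (xt @ xt)
            preds[i] = ym + ys * slope * (x[i] - xm) / xs
        expected = np.sqrt(np.mean((y - preds) ** 2))
        cv = loocv_rmsecv(x[:, None], y, 1)
        np.testing.assert_allclose(cv.per_sample_predictions, preds, atol=1e-12)
        assert cv.rmsecv == pytest.approx(expected, abs=1e-12)
        # invariant: rmsecv recomputable from the stored predictions
        assert cv.rmsecv == pytest.approx(
            np.sqrt(np.mean((y - cv.per_sample_predictions) ** 2)), abs=1e-15
        )

    def test_noiseless_linear_signal_near_zero_error(self, rng):
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 10
        assert loocv_rmsecv(X, y, 3).rmsecv < 1e-6

    def test_constant_response_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValidationError, match="constant"):
            loocv_rmsecv(X, np.ones(5), 1)

    def test_infeasible_fold_component_count_rejected(self, rng):
        X = rng.normal(size=(4, 5))
        y = rng.normal(size=4)
        with pytest.raises(ValidationError):
            loocv_rmsecv(X, y, 3)  # folds have 3 samples -> max 2 components

    def test_invariant_to_feature_order_and_affine_rescaling(self, rng):
        X = rng.normal(size=(12, 4))
        y = X @ np.array([1.0, 0.5, -1.0, 2.0]) + rng.normal(size=12)
        base = loocv_rmsecv(X, y, 2).rmsecv
        perm = loocv_rmsecv(X[:, [3, 1, 0, 2]], y, 2).rmsecv
        rescaled = loocv_rmsecv(X * [10.0, 0.2, 3.0, 1.0] + [5, -2, 0, 1], y, 2).rmsecv
        assert perm == pytest.approx(base, abs=1e-10)
        assert rescaled == pytest.approx(base, abs=1e-10)


class TestSelectComponents:
    def test_single_latent_direction_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = rng.normal(size=20)
            # one informative latent direction buried in feature-level noise
            X = np.outer(t, rng.normal(size=8)) + rng.normal(size=(20, 8))
            y = t + rng.normal(size=20)
            if select_components(X, y) == 1:
                hits += 1
        assert hits >= 9

    def test_max_one_returns_one(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        assert select_components(X, y, max_components=1) == 1

    def test_duplicated_feature_tie_prefers_fewer_components(self, rng):
        x = rng.normal(size=10)
        y = 2 * x + rng.normal(size=10) * 0.1
        X = np.column_stack([x, x])  # rank 1: component 2 adds nothing
        assert select_components(X, y) == 1


class TestPermutationTest:
    def test_reproducible_under_fixed_seed_and_exact_fraction(self, rng):
        X = rng.normal(size=(12, 5))
        y = X[:, 0] + rng.normal(size=12)
        a = permutation_test(X, y, B=30, seed=9)
        b = permutation_test(X, y, B=30, seed=9)
        np.testing.assert_array_equal(a.permuted_rmsecvs, b.permuted_rmsecvs)
        assert a.p_value == (a.permuted_rmsecvs < a.observed_rmsecv).sum() / 30
        smoothed = permutation_test(X, y, B=30, seed=9, smoothed=True)
        assert smoothed.p_value == pytest.approx(
            ((a.permuted_rmsecvs < a.observed_rmsecv).sum() + 1) / 31
        )

    def test_invalid_b_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValidationError):
            permutation_test(X, rng.normal(size=6), B=0)


class TestModelResultsSurface:
    def test_from_dataframe_and_summary(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(12, 3)), columns=["hsa-miR-1-5p", "hsa-miR-2-5p", "hsa-miR-3-3p"]
        )
        df["tg"] = df["hsa-miR-1-5p"] * 2 + rng.normal(size=12) * 0.1
        res = PLS1Model.from_dataframe(df, response="tg").fit()
        assert list(res.params.index) == list(df.columns[:3])
        text = res.summary()
        assert "RMSECV" in text and "hsa-miR-1-5p" in text
        assert res.vip().idxmax() == "hsa-miR-1-5p"

    def test_predict_new_samples_in_response_units(self, rng):
        X = rng.normal(size=(15, 4))
        y = X @ np.array([3.0, 0, 0, -1.0]) + 100
        res = PLS1Model(y, X).fit(n_components=4)
        Xnew = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            res.predict(Xnew), Xnew @ np.array([3.0, 0, 0, -1.0]) + 100, atol=1e-6
        )
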