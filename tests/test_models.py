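import itertools
import warnings

import numpy as np
import pytest
from sklearn.base import clone

from panelgfr import (
    MARKERS,
    PanelGFREstimator,
    choose_k,
    estimate,
    fit_model_bank,
    fit_reference,
    method_grid,
    predict_knn_marginalized,
    predict_screened,
    predict_weighted_trimmed,
)

from conftest import make_noiseless_cohort

P = len(MARKERS)


@pytest.fixture(scope="module")
def bank(dev_xy):
    return fit_model_bank(dev_xy, k=5)


@pytest.fixture(scope="module")
def ref(dev_xy):
    return fit_reference(dev_xy[0])


class TestFitModelBank:
    def test_exact_univariate_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (200, P))
        y = 2.0 * X[:, 0]
        bank = fit_model_bank((X, y))
        assert bank.univariate[0, 1] == pytest.approx(2.0)
        assert bank.univariate[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_uncorrelated_marker_gets_zero_weight(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (5000, P))
        y = X[:, 0] + 0.1 * rng.normal(size=5000)
        bank = fit_model_bank((X, y))
        assert bank.weights[0] > 0.9
        assert np.all(bank.weights[1:] < 0.1)

    def test_full_model_dominates_univariates_in_sample(self, dev_xy, bank):
        X, y = dev_xy
        full_rmse = np.sqrt(np.mean((y - bank.predict_full(X)) ** 2))
        ghat = bank.univariate_estimates(X)
        uni_rmse = np.sqrt(np.mean((y[:, None] - ghat) ** 2, axis=0))
        assert np.all(full_rmse <= uni_rmse + 1e-12)

    def test_prefit_enumerates_28_six_marker_models(self, dev_xy):
        bank = fit_model_bank(dev_xy, k=5, prefit_subsets=True)
        assert len(bank.subsets) == 28
        assert set(bank.subsets) == set(itertools.combinations(range(8), 6))

    def test_json_round_trip(self, bank, tmp_path, dev_xy):
        path = tmp_path / "bank.json"
        bank.prefit_six_marker_models()
        bank.to_json(path)
        from panelgfr import ModelBank

        back = ModelBank.from_json(path)
        X = dev_xy[0][:10]
        np.testing.assert_allclose(back.predict_full(X), bank.predict_full(X))
        np.testing.assert_allclose(back.univariate_estimates(X),
                                   bank.univariate_estimates(X))


class TestChooseK:
    def test_singleton_grid(self, dev_xy):
        assert choose_k(dev_xy, k_grid=[5]) == 5

    def test_deterministic(self, dev_xy):
        a = choose_k(dev_xy, k_grid=[1, 5, 20], n_iterations=3, seed=4)
        b = choose_k(dev_xy, k_grid=[1, 5, 20], n_iterations=3, seed=4)
        assert a == b

    def test_noiseless_data_prefers_small_k(self):
        cohort = make_noiseless_cohort(n=300, seed=2)
        k = choose_k((cohort.X(), cohort.y()), k_grid=[1, 3, 5, 50, 100],
                     n_iterations=5, seed=0)
        assert k <= 5


class TestWeightedTrimmed:
    def test_equal_weights_simple_mean(self, bank):
        b = fit_model_bank((bank.dev_X, bank.dev_y), k=5)
        b.weights = np.ones(P)
        ghat = np.full(P, 4.0)
        ghat[1] = 4.4
        assert predict_weighted_trimmed(b, ghat, [0, 1]) == pytest.approx(4.2)

    def test_single_marker_returns_its_estimate(self, bank):
        ghat = np.arange(P, dtype=float)
        assert predict_weighted_trimmed(bank, ghat, [3]) == pytest.approx(3.0)

    def test_hand_weighted_average(self, bank):
        b = fit_model_bank((bank.dev_X, bank.dev_y), k=5)
        b.weights = np.array([0.74, 0.58] + [0.0] * 6)
        ghat = np.array([4.0, 4.2] + [0.0] * 6)
        expected = (0.74 * 4.0 + 0.58 * 4.2) / 1.32
        assert predict_weighted_trimmed(b, ghat, [0, 1]) == pytest.approx(expected)
        assert expected == pytest.approx(4.0879, abs=1e-4)

    def test_zero_weights_fall_back_to_mean_with_warning(self, bank):
        b = fit_model_bank((bank.dev_X, bank.dev_y), k=5)
        b.weights = np.zeros(P)
        with pytest.warns(UserWarning, match="unweighted"):
            out = predict_weighted_trimmed(b, np.array([1.0] * 4 + [3.0] * 4),
                                           list(range(8)))
        assert out == pytest.approx(2.0)

    def test_convexity_of_clean_set_estimates(self, bank):
        rng = np.random.default_rng(8)
        for _ in range(50):
            ghat = rng.normal(4, 0.5, P)
            clean = rng.choice(P, size=rng.integers(1, P + 1), replace=False)
            est = predict_weighted_trimmed(bank, ghat, clean)
            assert ghat[clean].min() - 1e-12 <= est <= ghat[clean].max() + 1e-12


class TestKnnMarginalized:
    def test_all_markers_clean_equals_full_model(self, bank, dev_xy):
        x = dev_xy[0][3]
        assert predict_knn_marginalized(bank, x, range(P)) == pytest.approx(
            float(bank.predict_full(x)[0]))

    def test_exact_match_with_k1(self, dev_xy):
        bank = fit_model_bank(dev_xy, k=1)
        x = dev_xy[0][10]
        out = predict_knn_marginalized(bank, x, [0, 1, 2, 3, 4, 5])
        assert out == pytest.approx(float(bank.predict_full(dev_xy[0][10])[0]))

    def test_k_equal_to_dev_size_is_grand_mean(self, dev_xy):
        X, y = dev_xy
        bank = fit_model_bank((X[:100], y[:100]), k=100)
        grand = bank.predict_full(X[:100]).mean()
        a = predict_knn_marginalized(bank, X[200], [0, 1, 2])
        b = predict_knn_marginalized(bank, X[201], [5, 6])
        assert a == pytest.approx(grand)
        assert b == pytest.approx(grand)


class TestScreened:
    def test_full_set_equals_full_model(self, bank, dev_xy):
        x = dev_xy[0][7]
        assert predict_screened(bank, x, range(P)) == pytest.approx(
            float(bank.predict_full(x)[0]))

    def test_single_marker_equals_univariate(self, bank, dev_xy):
        x = dev_xy[0][9]
        expected = bank.univariate[0, 0] + bank.univariate[0, 1] * x[0]
        assert predict_screened(bank, x, [0]) == pytest.approx(expected)

    def test_matches_normal_equations_oracle(self, bank, dev_xy):
        """Subset models agree with an independent normal-equations solve."""
        X, y = bank.dev_X, bank.dev_y
        rng = np.random.default_rng(11)
        for _ in range(30):
            size = rng.integers(1, P + 1)
            subset = sorted(rng.choice(P, size=size, replace=False).tolist())
            A = np.column_stack([np.ones(len(X)), X[:, subset]])
            coef = np.linalg.solve(A.T @ A, A.T @ y)
            x = dev_xy[0][rng.integers(len(dev_xy[0]))]
            oracle = coef[0] + x[subset] @ coef[1:]
            assert predict_screened(bank, x, subset) == pytest.approx(
                oracle, abs=1e-8)

    def test_noiseless_six_marker_fit_is_exact(self):
        cohort = make_noiseless_cohort(n=120, seed=3)
        X, y = cohort.X(), cohort.y()
        bank = fit_model_bank((X, y))
        preds = np.array([predict_screened(bank, x, [0, 1, 2, 3, 4, 5]) for x in X])
        np.testing.assert_allclose(preds, y, atol=1e-8)


class TestEstimateDispatch:
    def test_grid_enumerates_nine_pairs(self):
        grid = method_grid()
        assert len(grid) == 9
        assert len(set(grid)) == 9
        assert len(method_grid(include_naive=True)) == 10

    def test_unknown_pair_raises(self, bank, ref, dev_xy):
        with pytest.raises(ValueError, match="unknown method pair"):
            estimate(bank, ref, dev_xy[0][:2], detection="univariate",
                     estimator="median")

    def test_estimates_within_sane_envelope(self, bank, ref, dev_xy):
        X, y = dev_xy
        lo, hi = y.mean() - 4 * y.std(), y.mean() + 4 * y.std()
        for det, est in method_grid(include_naive=True):
            out = estimate(bank, ref, X[:100], detection=det, estimator=est)
            assert np.isfinite(out).all()
            assert (out > lo).all() and (out < hi).all()

    def test_inside_ellipse_multivariate_equals_naive(self, bank, ref, dev_xy):
        from panelgfr import mahalanobis_d2

        X = dev_xy[0]
        inside = X[mahalanobis_d2(ref, X) <= ref.c][:20]
        screened = estimate(bank, ref, inside, detection="multivariate",
                            estimator="screened")
        naive = estimate(bank, ref, inside, detection="none", estimator="naive")
        np.testing.assert_allclose(screened, naive)

    def test_no_flagged_rows_match_untrimmed_forms(self, bank, ref, dev_xy):
        """Univariate detection with nothing flagged = plain estimators."""
        X = dev_xy[0]
        from panelgfr import detect_univariate

        flags = detect_univariate(ref, X).flags
        clean_rows = X[~flags.any(axis=1)][:30]
        knn = estimate(bank, ref, clean_rows, detection="univariate",
                       estimator="knn")
        np.testing.assert_allclose(knn, bank.predict_full(clean_rows))
        screened = estimate(bank, ref, clean_rows, detection="univariate",
                            estimator="screened")
        np.testing.assert_allclose(screened, bank.predict_full(clean_rows))

    def test_all_markers_flagged_falls_back_with_warning(self, bank, ref):
        x = np.full((1, P), 1e3)
        with pytest.warns(UserWarning, match="all markers flagged"):
            out = estimate(bank, ref, x, detection="univariate",
                           estimator="screened")
        assert np.isfinite(out).all()


class TestPanelGFREstimatorSklearn:
    def test_fit_predict_shapes_and_attributes(self, dev_xy):
        X, y = dev_xy
        est = PanelGFREstimator(detection="consistency", estimator="screened")
        est.fit(X, y)
        assert est.n_features_in_ == P
        assert hasattr(est, "bank_") and hasattr(est, "reference_")
        pred = est.predict(X[:15])
        assert pred.shape == (15,)
        assert np.allclose(est.predict_gfr(X[:15]), np.exp(pred))

    def test_clone_and_get_params(self, dev_xy):
        est = PanelGFREstimator(detection="univariate", estimator="trimmed", k=7)
        cloned = clone(est)
        assert cloned.get_params()["k"] == 7
        assert cloned.get_params()["detection"] == "univariate"

    def test_naive_matches_linear_regression(self, dev_xy):
        from sklearn.linear_model import LinearRegression

        X, y = dev_xy
        est = PanelGFREstimator(detection="none", estimator="naive").fit(X, y)
        lr = LinearRegression().fit(X, y)
        np.testing.assert_allclose(est.predict(X[:20]), lr.predict(X[:20]),
                                   atol=1e-8)

    def test_wrong_column_count_raises(self, dev_xy):
        X, y = dev_xy
        with pytest.raises(ValueError, match="marker columns"):
            PanelGFREstimator().fit(X[:, :5], y)
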