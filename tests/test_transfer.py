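import dataclasses

import numpy as np
import pytest
from sklearn.base import clone

from panelgfr import (
    MARKERS,
    TransferConfig,
    TransferGFREstimator,
    TransferModel,
    default_design,
    detect_transferable,
    fit_model_bank,
    fit_transfer,
    fit_transfer_robust,
    generate_cohort,
    predict_transfer,
)
from panelgfr.models import _ols, estimate
from panelgfr.outliers import fit_reference

P = len(MARKERS)


@pytest.fixture(scope="module")
def profile():
    return default_design(seed=0).profile("MESA")


@pytest.fixture(scope="module")
def target_xy(profile):
    cohort = generate_cohort(dataclasses.replace(profile, n=400), seed=21)
    return cohort.X(), cohort.y()


@pytest.fixture(scope="module")
def identical_source(profile):
    cohort = generate_cohort(dataclasses.replace(profile, n=800), seed=22)
    return cohort.X(), cohort.y()


def adversarial_profile(profile, n=800):
    """Same marginals, sign-flipped marker/GFR slopes."""
    return dataclasses.replace(
        profile, n=n,
        beta={m: -b for m, b in profile.beta.items()},
        alpha={m: profile.alpha[m] + 2 * profile.beta[m] * profile.mu_g
               for m in MARKERS})


class TestTwoStepDecomposition:
    def test_beta_is_w_plus_delta_exactly(self, target_xy, identical_source):
        model = fit_transfer({"s": identical_source},
                             (target_xy[0][:50], target_xy[1][:50]), seed=0)
        np.testing.assert_array_equal(model.beta, model.w + model.delta)

    def test_no_sources_degenerates_to_target_only(self, target_xy):
        X, y = target_xy[0][:60], target_xy[1][:60]
        model = fit_transfer({}, (X, y), seed=1)
        assert model.sources_used == ()
        # pooled stage saw target only; same penalized pipeline either way
        from panelgfr.transfer import _penalized_fit

        own = _penalized_fit(X, y, TransferConfig(), 1)
        resid = y - (own[0] + X @ own[1:])
        np.testing.assert_allclose(model.w, own)

    def test_ols_mode_reduces_to_target_ols(self, target_xy):
        """Unpenalized two-step: bias correction absorbs the pooled fit."""
        X, y = target_xy[0][:80], target_xy[1][:80]
        config = TransferConfig(penalty="none")
        model = fit_transfer({}, (X, y), config=config, seed=2)
        np.testing.assert_allclose(model.beta, _ols(X, y), atol=1e-8)


class TestPredictTransfer:
    def test_zero_delta_equals_pooled_stage(self):
        model = TransferModel(w=np.arange(9, dtype=float),
                              delta=np.zeros(9), sources_used=(),
                              config=TransferConfig())
        X = np.random.default_rng(0).normal(size=(5, P))
        np.testing.assert_allclose(predict_transfer(model, X),
                                   model.w[0] + X @ model.w[1:])

    def test_intercept_only_model_is_constant(self):
        beta = np.zeros(9)
        beta[0] = 3.7
        model = TransferModel(w=beta, delta=np.zeros(9), sources_used=(),
                              config=TransferConfig())
        out = predict_transfer(model, np.ones((4, P)))
        np.testing.assert_allclose(out, 3.7)

    def test_hand_vector_arithmetic(self):
        w = np.zeros(9)
        w[0], w[1] = 1.0, 0.5
        model = TransferModel(w=w, delta=np.zeros(9), sources_used=(),
                              config=TransferConfig())
        x = np.zeros((1, P))
        x[0, 0] = 2.0
        assert predict_transfer(model, x)[0] == pytest.approx(2.0)


class TestDetectTransferable:
    def test_zero_sources_gives_empty_set(self, target_xy):
        assert detect_transferable({}, (target_xy[0][:30], target_xy[1][:30])) == []

    def test_target_too_small_raises(self, target_xy):
        with pytest.raises(ValueError, match="too small"):
            detect_transferable({"s": target_xy},
                                (target_xy[0][:5], target_xy[1][:5]))

    def test_identical_source_is_kept(self, target_xy, identical_source):
        kept_count = 0
        for seed in range(10):
            kept = detect_transferable({"s": identical_source},
                                       (target_xy[0][:25], target_xy[1][:25]),
                                       seed=seed)
            kept_count += kept == ["s"]
        assert kept_count >= 9

    def test_sign_flipped_source_is_excluded(self, profile, target_xy):
        adv = generate_cohort(adversarial_profile(profile), seed=23)
        excluded = 0
        for seed in range(10):
            kept = detect_transferable({"adv": (adv.X(), adv.y())},
                                       (target_xy[0][:25], target_xy[1][:25]),
                                       seed=seed)
            excluded += kept == []
        assert excluded >= 9

    def test_deterministic_for_seed(self, target_xy, identical_source):
        args = ({"s": identical_source}, (target_xy[0][:30], target_xy[1][:30]))
        assert detect_transferable(*args, seed=7) == detect_transferable(*args, seed=7)


class TestTransferAccuracy:
    def test_transfer_beats_small_target_ols(self, profile, identical_source):
        """With rich identical-distribution sources, transfer helps at n=25."""
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            cohort = generate_cohort(dataclasses.replace(profile, n=325),
                                     seed=500 + rep)
            X, y = cohort.X(), cohort.y()
            tr, te = np.arange(25), np.arange(25, 325)
            model = fit_transfer({"s": identical_source}, (X[tr], y[tr]),
                                 seed=rep)
            own = _ols(X[tr], y[tr])
            rmse_t = np.sqrt(np.mean((y[te] - model.predict(X[te])) ** 2))
            rmse_o = np.sqrt(np.mean((y[te] - own[0] - X[te] @ own[1:]) ** 2))
            wins += rmse_t < rmse_o
        assert wins >= 8

    def test_adversarial_sources_do_no_harm_on_average(self, profile):
        """Negative-transfer guard: flipped-slope sources are screened out."""
        adv = generate_cohort(adversarial_profile(profile), seed=29)
        rmse_t, rmse_o = [], []
        for rep in range(10):
            cohort = generate_cohort(dataclasses.replace(profile, n=325),
                                     seed=900 + rep)
            X, y = cohort.X(), cohort.y()
            tr, te = np.arange(25), np.arange(25, 325)
            model = fit_transfer({"adv": (adv.X(), adv.y())}, (X[tr], y[tr]),
                                 seed=rep)
            own = _ols(X[tr], y[tr])
            rmse_t.append(np.sqrt(np.mean((y[te] - model.predict(X[te])) ** 2)))
            rmse_o.append(np.sqrt(np.mean((y[te] - own[0] - X[te] @ own[1:]) ** 2)))
        assert np.mean(rmse_t) <= 1.1 * np.mean(rmse_o)


class TestRobustTransfer:
    def test_double_degeneracy_equals_target_screened(self, target_xy):
        """No sources + unpenalized fits = plain screened estimation."""
        X, y = target_xy[0][:120], target_xy[1][:120]
        bank = fit_model_bank((X, y))
        ref = fit_reference(X)
        config = TransferConfig(penalty="none")
        predictor = fit_transfer_robust({}, (X, y), bank, config=config, seed=0)
        X_app = target_xy[0][150:200]
        np.testing.assert_allclose(
            predictor.predict(X_app),
            estimate(bank, ref, X_app, detection="consistency",
                     estimator="screened"),
            atol=1e-8)

    def test_screening_avoids_contaminated_markers(self, profile, identical_source):
        from panelgfr import ContaminationSpec, contaminate
        from panelgfr.outliers import select_consistent_matrix

        cohort = generate_cohort(dataclasses.replace(profile, n=400), seed=31)
        X, y = cohort.X(), cohort.y()
        bank = fit_model_bank((X[:100], y[:100]))
        spec = ContaminationSpec(markers=("pseudouridine", "cystatin_c"),
                                 fraction=1.0, seed=32)
        Xc, _ = contaminate(X[100:], X[:100].mean(axis=0),
                            X[:100].std(axis=0, ddof=1), spec)
        subsets = select_consistent_matrix(bank.univariate_estimates(Xc))
        pj, cj = MARKERS.index("pseudouridine"), MARKERS.index("cystatin_c")
        excl = np.mean([(pj not in s) or (cj not in s) for s in subsets])
        assert excl >= 0.8


class TestTransferGFREstimatorSklearn:
    def test_fit_predict_and_attributes(self, target_xy, identical_source):
        est = TransferGFREstimator(sources={"s": identical_source},
                                   random_state=0)
        X, y = target_xy[0][:40], target_xy[1][:40]
        est.fit(X, y)
        assert est.coef_.shape == (P,)
        np.testing.assert_allclose(est.coef_, est.w_[1:] + est.delta_[1:])
        pred = est.predict(target_xy[0][40:60])
        assert pred.shape == (20,)

    def test_cloneable(self, identical_source):
        est = TransferGFREstimator(sources={"s": identical_source}, epsilon0=0.05)
        assert clone(est).get_params()["epsilon0"] == 0.05
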