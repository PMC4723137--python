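"""Logistic fitting (IRLS), built-in coefficient sets, ROC/Youden analysis."""

import numpy as np
import pytest

from marginmap.classify import (
    BinLogisticRegression,
    LogisticModel,
    REFERENCE_MODELS,
    SingleClassError,
    classify_bins,
    feature_matrix,
    fit_logistic,
    predict_prob,
    predict_probs,
    reference_model,
    roc,
)
from marginmap.features import BinFeatures


def make_bin(af=0.1, d=8.0, s=1.0, n=3, empty=False):
    return BinFeatures(
        bin_row=0, bin_col=0, area_fraction=af, avg_diameter_um=d,
        avg_shape_per_um=s, n_regions=n, empty=empty,
    )


class TestReferenceModels:
    def test_three_variable_worked_example(self):
        m = reference_model("af_diameter_shape")
        eta = m.linear_predictor(np.array([0.2, 10.0, 0.9]))[0]
        assert eta == pytest.approx(1.0751, abs=1e-4)
        assert m.prob(np.array([0.2, 10.0, 0.9]))[0] == pytest.approx(0.7456, abs=2e-4)

    def test_all_four_subsets_present(self):
        assert set(REFERENCE_MODELS) == {
            "af_diameter_shape", "af_diameter", "af_shape", "diameter_shape",
        }
        for m in REFERENCE_MODELS.values():
            assert len(m.betas) == len(m.feature_subset)
            assert m.units == "px"

    def test_monotonicity_in_each_feature(self):
        """p rises with area fraction, falls with diameter and shape."""
        m = reference_model("af_diameter_shape")
        base = np.array([0.1, 8.0, 1.0])
        p0 = m.prob(base)[0]
        assert m.prob(base + [0.05, 0, 0])[0] > p0
        assert m.prob(base + [0, 1.0, 0])[0] < p0
        assert m.prob(base + [0, 0, 0.5])[0] < p0

    def test_json_roundtrip(self):
        m = reference_model("af_shape")
        back = LogisticModel.from_json(m.to_json())
        assert back == m


class TestPredict:
    def test_zero_model_gives_half(self):
        m = LogisticModel(("area_fraction",), 0.0, (0.0,))
        assert predict_prob(m, make_bin()) == 0.5

    def test_empty_bin_returns_zero(self):
        m = reference_model()
        assert predict_prob(m, make_bin(af=0, d=0, s=0, n=0, empty=True)) == 0.0

    def test_overlap_only_bin_returns_zero(self):
        # no centroid-assigned region -> diameter/shape undefined -> 0
        m = reference_model()
        assert predict_prob(m, make_bin(af=0.01, d=0, s=0, n=0, empty=False)) == 0.0

    def test_pixel_unit_conversion_uses_pitch(self):
        m = reference_model()  # px units
        b = make_bin(af=0.2, d=15.0, s=0.6)  # um features
        # at pitch 1.5: D_px = 10, S_px = 0.9 -> the worked example
        assert predict_prob(m, b, pitch_um=1.5) == pytest.approx(0.7456, abs=2e-4)


class TestFit:
    def test_symmetric_data_zero_intercept(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(400, 1))
        X = np.vstack([x, -x])
        y = np.r_[np.ones(400), np.zeros(400)]
        est = BinLogisticRegression().fit(X, y)
        assert abs(est.intercept_) < 1e-6

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] + rng.normal(scale=2, size=200) > 0).astype(float)
        b1 = BinLogisticRegression().fit(X, y)
        b2 = BinLogisticRegression().fit(np.vstack([X, X]), np.r_[y, y])
        assert np.allclose(
            np.r_[b1.intercept_, b1.coef_], np.r_[b2.intercept_, b2.coef_], atol=1e-7
        )

    def test_parameter_recovery_within_three_se(self):
        """n=5000 draws from the reference three-variable coefficients."""
        rng = np.random.default_rng(11)
        n = 5000
        X = np.column_stack(
            [rng.uniform(0, 0.25, n), rng.uniform(2, 12, n), rng.uniform(0.3, 3, n)]
        )
        beta = np.array([2.659, 44.074, -0.962, -0.8652])
        p = 1 / (1 + np.exp(-(beta[0] + X @ beta[1:])))
        y = (rng.uniform(size=n) < p).astype(float)
        est = BinLogisticRegression().fit(X, y)
        b = np.r_[est.intercept_, est.coef_]
        assert est.converged_ and not est.separated_
        assert np.all(np.abs(b - beta) <= 3 * est.bse_)

    def test_matches_statsmodels_glm(self):
        """Independent IRLS oracle: statsmodels Binomial GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 3))
        y = (X @ [1.0, -0.5, 0.2] + rng.logistic(size=300) > 0).astype(float)
        est = BinLogisticRegression().fit(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.allclose(np.r_[est.intercept_, est.coef_], ref.params, atol=1e-8)
        assert np.allclose(np.r_[est.bse_], ref.bse, rtol=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            BinLogisticRegression().fit(np.zeros((5, 1)), np.ones(5))
        with pytest.raises(SingleClassError):
            fit_logistic([make_bin()] * 4, [1, 1, 1, 1])

    def test_complete_separation_flagged(self):
        X = np.r_[np.linspace(1, 2, 20), np.linspace(3, 4, 20)].reshape(-1, 1)
        y = np.r_[np.zeros(20), np.ones(20)]
        est = BinLogisticRegression().fit(X, y)
        assert est.separated_
        assert np.all(np.isfinite(np.r_[est.intercept_, est.coef_]))

    def test_ridge_fallback_on_separation(self):
        X = np.r_[np.linspace(1, 2, 20), np.linspace(3, 4, 20)].reshape(-1, 1)
        y = np.r_[np.zeros(20), np.ones(20)]
        est = BinLogisticRegression(ridge_on_separation=1.0).fit(X, y)
        assert est.separated_ and est.converged_
        assert abs(est.coef_[0]) < 50

    def test_fit_logistic_excludes_empty_bins_and_records_units(self):
        rng = np.random.default_rng(3)
        feats, labels = [], []
        for i in range(120):
            tumor = i % 2
            feats.append(make_bin(af=0.05 + 0.1 * tumor + rng.normal(0, 0.01)))
            labels.append(tumor)
        feats += [make_bin(af=0, d=0, s=0, n=0, empty=True)] * 10
        labels += [0] * 10
        m = fit_logistic(feats, labels, feature_subset=("area_fraction",))
        assert m.meta["n_obs"] == 120
        assert m.units == "um"
        assert m.betas[0] > 0  # higher area fraction -> tumor

    def test_sklearn_get_set_params(self):
        est = BinLogisticRegression(tol=1e-6)
        assert est.get_params()["tol"] == 1e-6
        est.set_params(max_iter=50)
        assert est.max_iter == 50


class TestROC:
    def test_perfect_separation(self):
        assert roc([0.9, 0.8], [1, 0]).auc == 1.0

    def test_four_point_worked_example(self):
        r = roc([0.9, 0.7, 0.4, 0.2], [1, 0, 1, 0])
        assert r.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc([0.3] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_with_sklearn_crosscheck(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for _ in range(10):
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            p = np.round(rng.uniform(size=60), 2)  # force ties
            assert roc(p, y).auc == pytest.approx(roc_auc_score(y, p), abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = rng.uniform(size=50)
        assert roc(p, y).auc == pytest.approx(roc(p**3, y).auc, abs=1e-12)

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        p = rng.uniform(size=80)
        r = roc(p, y)
        assert np.all(np.diff(r.sensitivity) >= 0)  # thresholds descend

    def test_youden_tiebreak_prefers_lower_alpha(self):
        # two thresholds achieve J = 1 on duplicated perfect data
        r = roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        js = r.sensitivity + r.specificity - 1
        best = js.max()
        alphas_at_best = r.thresholds[js == best]
        assert r.youden_alpha == alphas_at_best.min()

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc([0.1, 0.9], [1, 1])


class TestClassifyBins:
    def test_boundary_behavior(self):
        assert classify_bins([0.51, 0.50, 0.49], 0.5).tolist() == [1, 0, 0]
        assert classify_bins([0.3, 0.9], 1.0).tolist() == [0, 0]
        assert classify_bins([0.0, 0.2], 0.0).tolist() == [0, 1]

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            classify_bins([0.5], 1.5)


def test_feature_matrix_units():
    b = make_bin(af=0.2, d=15.0, s=0.6)
    um = feature_matrix([b], units="um", pitch_um=1.5)
    px = feature_matrix([b], units="px", pitch_um=1.5)
    assert um.tolist() == [[0.2, 15.0, 0.6]]
    assert px.tolist() == [[0.2, 10.0, pytest.approx(0.9)]]


def test_four_subsets_fit_and_beat_chance(training_set):
    """Each variable subset fits on the synthetic training bins and its ROC
    dominates chance."""
    feats = training_set["features"]
    labels = training_set["labels"]
    keep = [not f.empty for f in feats]
    kept = [f for f, k in zip(feats, keep) if k]
    y = labels[np.array(keep)]
    for name, ref in REFERENCE_MODELS.items():
        m = fit_logistic(kept, y, feature_subset=ref.feature_subset)
        probs = predict_probs(m, kept)
        assert roc(probs, y).auc > 0.6, name
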