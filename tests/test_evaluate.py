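import numpy as np
import pandas as pd
import pytest

from habitatrad.evaluate import (
    auc_delong,
    case_total_points,
    classification_metrics,
    delong_paired,
    hosmer_lemeshow,
    net_benefit,
    nomogram_points,
    shap_attributions,
    youden_threshold,
)
from habitatrad.models import TrainedModel, fit_signature_model, predict_prob


def brute_auc(probs, labels):
    """Exhaustive concordant-pair count with ties at 1/2."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAucDelong:
    def test_perfect_ranking(self):
        auc, lo, hi = auc_delong([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and hi == 1.0

    def test_hand_counted_three_quarters(self):
        # positives {0.9, 0.6}, negatives {0.7, 0.1}: 3 of 4 pairs concordant
        auc, lo, hi = auc_delong([0.9, 0.6, 0.7, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)
        assert lo <= auc <= hi

    def test_matches_exhaustive_pair_count(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 31))
            y = rng.integers(0, 2, n)
            y[0], y[1] = 0, 1
            p = np.round(rng.random(n), 2)  # rounded to force ties
            assert auc_delong(p, y)[0] == pytest.approx(brute_auc(p, y))

    def test_se_matches_stratified_bootstrap(self, rng):
        n = 100
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        p = np.clip(0.5 + 0.25 * y + 0.2 * rng.normal(size=n), 0, 1)
        auc, lo, hi = auc_delong(p, y)
        se_delong = (hi - lo) / (2 * 1.96)
        boots = []
        br = np.random.default_rng(0)
        pos, neg = p[y == 1], p[y == 0]
        for _ in range(2000):
            bp = np.r_[pos[br.integers(0, 40, 40)], neg[br.integers(0, 60, 60)]]
            boots.append(auc_delong(bp, y)[0])
        se_boot = np.std(boots)
        assert abs(se_delong - se_boot) / se_boot < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([0.5, 0.6], [1, 1])


class TestDelongPaired:
    def test_identical_vectors_p_one(self, rng):
        p = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        assert delong_paired(p, p, y) == 1.0

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest
        ps = []
        r = np.random.default_rng(11)
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        for _ in range(300):
            ps.append(delong_paired(r.random(200), r.random(200), y))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_informative_vs_random_significant(self, rng):
        n = 200
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        good = y + 0.3 * rng.normal(size=n)
        rand = rng.random(n)
        assert delong_paired(good, rand, y) < 0.05


class TestClassificationMetrics:
    def test_hand_counted_confusion(self):
        # TP=3, FP=1, FN=1, TN=5 at threshold 0.5
        probs = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.2, 0.3, 0.4, 0.45]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        m = classification_metrics(probs, labels, 0.5)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 1, 1, 5)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(5 / 6)

    def test_perfect_classifier(self):
        m = classification_metrics([0.9, 0.9, 0.1], [1, 1, 0], 0.5)
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"))

    def test_threshold_zero(self):
        m = classification_metrics([0.3, 0.6], [1, 0], 0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_undefined_ratio_is_nan(self):
        m = classification_metrics([0.9, 0.8], [1, 1], 0.5)
        assert np.isnan(m["npv"])  # empty predicted-negative set

    def test_youden_threshold_optimal(self, rng):
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        p = np.clip(0.3 + 0.4 * y + 0.1 * rng.normal(size=60), 0, 1)
        t = youden_threshold(p, y)
        m = classification_metrics(p, y, t)
        best = m["sensitivity"] + m["specificity"]
        for other in np.linspace(0.01, 0.99, 50):
            mo = classification_metrics(p, y, other)
            assert best >= mo["sensitivity"] + mo["specificity"] - 1e-12


class TestHosmerLemeshow:
    def test_perfectly_calibrated_bins_statistic_zero(self):
        # within every bin the observed rate equals the constant prediction
        probs = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
        labels = np.concatenate([
            [1] * 2 + [0] * 8, [1] * 4 + [0] * 6, [1] * 6 + [0] * 4, [1] * 8 + [0] * 2,
        ])
        stat, p = hosmer_lemeshow(probs, labels, groups=2)
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_two_bin_hand_computation(self):
        probs = np.r_[np.full(10, 0.25), np.full(10, 0.75)]
        labels = np.r_[np.ones(5, int), np.zeros(5, int), np.ones(5, int), np.zeros(5, int)]
        stat, p = hosmer_lemeshow(probs, labels, groups=2)
        # bin1: O=5, E=2.5, var=2.5*(1-0.25)=1.875 ; bin2: O=5, E=7.5, var=1.875
        expected = (5 - 2.5) ** 2 / 1.875 + (5 - 7.5) ** 2 / 1.875
        assert stat == pytest.approx(expected)

    def test_type_i_error_rate_near_alpha(self):
        """On correctly specified logistic data with the model re-fit per
        replicate, the HL test at chi2(g-2) rejects at roughly the nominal
        5% (the decile-based HL is known to run slightly liberal)."""
        import statsmodels.api as sm
        rejections = 0
        reps = 200
        r = np.random.default_rng(5)
        for _ in range(reps):
            x = r.normal(size=500)
            p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
            y = (r.random(500) < p).astype(int)
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            _, pv = hosmer_lemeshow(fit.predict(), y)
            rejections += pv < 0.05
        assert 0.02 <= rejections / reps <= 0.095


class TestNetBenefit:
    def test_treat_none_zero_everywhere(self, rng):
        y = rng.integers(0, 2, 50)
        curve = net_benefit(rng.random(50), y)
        assert (curve["treat_none"] == 0).all()

    def test_hand_computed_point(self):
        # N=10, 4 positives; 5 predicted positive (TP=3, FP=2), t=0.2:
        # NB = 0.3 - 0.2 * 0.25 = 0.25
        probs = [0.9, 0.8, 0.7, 0.1, 0.6, 0.5, 0.15, 0.1, 0.05, 0.0]
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        curve = net_benefit(probs, labels, thresholds=[0.2])
        assert curve.loc[0, "model"] == pytest.approx(0.3 - 0.2 * (0.2 / 0.8))

    def test_perfect_classifier_nb_equals_prevalence(self):
        y = np.r_[np.ones(4, int), np.zeros(6, int)]
        p = y.astype(float)
        curve = net_benefit(p, y)
        assert np.allclose(curve["model"], 0.4)

    def test_calibrated_model_not_below_treat_none_at_own_threshold(self, rng):
        x = rng.normal(size=400)
        p = 1 / (1 + np.exp(-x))
        y = (rng.random(400) < p).astype(int)
        curve = net_benefit(p, y)
        assert (curve["model"] >= -1e-3).all()


class TestShap:
    def test_linear_closed_form_and_additivity(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = (X["a"] + 0.5 * X["b"] + 0.1 * rng.normal(size=30) > 0).astype(int)
        model = fit_signature_model(X, y, algorithm="logistic", seed=0)
        attr, base = shap_attributions(model, X, X.iloc[:5])
        # closed form: w_j (z_j - mean background z_j)
        Z = (X.to_numpy() - model.feature_means) / model.feature_sds
        expect = (Z[:5] - Z.mean(axis=0)) * model.coef
        np.testing.assert_allclose(attr, expect, atol=1e-10)
        eta = model.intercept + Z[:5] @ model.coef
        np.testing.assert_allclose(base + attr.sum(axis=1), eta, atol=1e-6)

    def test_zero_coefficient_zero_attribution(self, rng):
        model = TrainedModel("logistic", {}, ["a", "b"], np.zeros(2), np.ones(2),
                             coef=np.array([1.5, 0.0]), intercept=0.2)
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        attr, _ = shap_attributions(model, X, X)
        assert np.allclose(attr[:, 1], 0.0)

    def test_tree_model_additivity_within_tolerance(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = (X["a"] > 0).astype(int)
        model = fit_signature_model(X, y, algorithm="extra-trees",
                                    grid={"n_estimators": [50], "max_depth": [3]}, seed=0)
        cases = X.iloc[:3]
        attr, base = shap_attributions(model, X, cases, seed=0, n_coalitions=256)
        out = predict_prob(model, cases)
        np.testing.assert_allclose(base + attr.sum(axis=1), out, atol=1e-2)

    def test_empty_background_rejected(self, rng):
        model = TrainedModel("logistic", {}, ["a"], np.zeros(1), np.ones(1),
                             coef=np.array([1.0]))
        X = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            shap_attributions(model, X.iloc[:0], X)


class TestNomogram:
    def _model(self):
        return TrainedModel(
            "stepwise-logistic", {}, ["u", "v"],
            np.array([0.0, 0.0]), np.array([1.0, 1.0]),
            coef=np.array([2.0, 1.0]), intercept=-0.5,
        )

    def test_proportional_point_scaling(self):
        nomo = nomogram_points(self._model(), {"u": (0.0, 1.0), "v": (0.0, 1.0)})
        pts = {t["term"]: t["points_max"] for t in nomo["terms"]}
        assert pts["u"] == pytest.approx(100.0)
        assert pts["v"] == pytest.approx(50.0)

    def test_lookup_consistent_with_predict_prob(self):
        model = self._model()
        nomo = nomogram_points(model, {"u": (0.0, 1.0), "v": (0.0, 1.0)})
        case = {"u": 0.3, "v": 0.8}
        total = case_total_points(nomo, case)
        prob_direct = predict_prob(model, pd.DataFrame([case]))[0]
        eta = nomo["base_eta"] + total * nomo["points_unit_logodds"]
        assert 1 / (1 + np.exp(-eta)) == pytest.approx(prob_direct, abs=1e-6)

    def test_zero_range_term_warns(self):
        with pytest.warns(UserWarning, match="zero contribution"):
            nomogram_points(self._model(), {"u": (0.5, 0.5), "v": (0.0, 1.0)})
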