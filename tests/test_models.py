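import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from habitatrad.models import (
    DEFAULT_GRIDS,
    TrainedModel,
    encode_clinical,
    fit_clinical_model,
    fit_combined_model,
    fit_signature_model,
    predict_prob,
    stratified_split,
)


class TestStratifiedSplit:
    def test_exact_proportional_allocation(self, rng):
        ids = [f"c{i}" for i in range(100)]
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        split = stratified_split(ids, y, ratio=0.7, seed=0)
        assert len(split.train_ids) == 70 and len(split.validation_ids) == 30
        lab = dict(zip(ids, y))
        assert sum(lab[i] for i in split.train_ids) == 28
        assert sum(lab[i] for i in split.validation_ids) == 12

    def test_disjoint_exhaustive(self, rng):
        ids = list(range(37))
        y = rng.integers(0, 2, 37)
        y[:3], y[-3:] = 0, 1
        split = stratified_split(ids, y, ratio=0.7, seed=4)
        assert set(split.train_ids) | set(split.validation_ids) == set(ids)
        assert not set(split.train_ids) & set(split.validation_ids)

    def test_reproducible(self):
        ids = list(range(30))
        y = [0, 1] * 15
        a = stratified_split(ids, y, seed=9)
        b = stratified_split(ids, y, seed=9)
        assert a.train_ids == b.train_ids

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([1, 2, 3, 4], [0, 0, 1, 1], ratio=1.5)


@pytest.fixture
def separable_data(rng):
    n = 40
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    X = pd.DataFrame({"a": y * 4.0 + rng.normal(0, 0.1, n),
                      "b": rng.normal(size=n)})
    return X, y


class TestSignatureModel:
    @pytest.mark.parametrize("algorithm", ["logistic", "linear-SVM", "extra-trees"])
    def test_separable_data_perfect_training_auc(self, separable_data, algorithm):
        X, y = separable_data
        model = fit_signature_model(X, y, algorithm=algorithm, seed=0)
        p = predict_prob(model, X)
        from habitatrad.evaluate import auc_delong
        assert auc_delong(p, y)[0] == 1.0

    def test_supported_algorithm_set(self):
        assert set(DEFAULT_GRIDS) == {"logistic", "linear-SVM", "extra-trees"}

    def test_permuted_labels_cv_auc_near_half(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 4)))
        y = rng.permutation(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)])
        model = fit_signature_model(X, y, algorithm="logistic", seed=1)
        assert abs(model.cv_auc - 0.5) < 0.12

    def test_empty_grid_rejected(self, separable_data):
        X, y = separable_data
        with pytest.raises(ValueError):
            fit_signature_model(X, y, algorithm="logistic", grid={"C": []})

    def test_svm_probabilities_calibrated_range(self, separable_data):
        X, y = separable_data
        model = fit_signature_model(X, y, algorithm="linear-SVM", seed=0)
        p = predict_prob(model, X)
        assert ((p >= 0) & (p <= 1)).all()
        assert model.calibration is not None

    def test_round_trip_identical_predictions(self, separable_data, tmp_path):
        X, y = separable_data
        for algorithm in ("linear-SVM", "extra-trees"):
            model = fit_signature_model(X, y, algorithm=algorithm, seed=0)
            path = str(tmp_path / f"m_{algorithm}.json")
            model.save(path)
            again = TrainedModel.load(path)
            np.testing.assert_allclose(predict_prob(again, X), predict_prob(model, X))


def oracle_univariate_or(x, y):
    """Single-covariate logistic OR by direct likelihood maximization."""
    def nll(params):
        b0, b1 = params
        eta = b0 + b1 * x
        return np.sum(np.log1p(np.exp(eta)) - y * eta)
    res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(np.exp(res.x[1]))


class TestClinicalModel:
    def test_constant_covariate_screened_out(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        clin = pd.DataFrame({
            "age": np.full(n, 50.0),
            "diameter": 10 + 10 * y + rng.normal(0, 2, n),
            "location": rng.integers(1, 5, n),
            "laterality": rng.integers(0, 2, n),
            "birads": rng.integers(3, 6, n),
        })
        model, report = fit_clinical_model(clin, y)
        assert report.loc["age", "p_value"] == 1.0
        assert "age" not in model.feature_names
        assert "diameter" in model.feature_names

    def test_univariate_or_matches_numeric_oracle(self, rng):
        n = 20
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(int)
        if len(np.unique(y)) < 2:
            y[0], y[-1] = 0, 1
        from habitatrad.models import _univariate_logistic
        orr, lo, hi, p = _univariate_logistic(x, y)
        assert orr == pytest.approx(oracle_univariate_or(x, y), rel=1e-3)
        assert lo < orr < hi

    def test_screen_report_columns(self, rng):
        n = 50
        y = rng.integers(0, 2, n)
        y[:5], y[-5:] = 0, 1
        clin = pd.DataFrame({
            "age": rng.normal(48, 10, n),
            "diameter": rng.normal(25, 10, n),
            "location": rng.integers(1, 5, n),
            "laterality": rng.integers(0, 2, n),
            "birads": rng.integers(3, 6, n),
        })
        _, report = fit_clinical_model(clin, y)
        assert list(report.columns) == ["OR", "CI_low", "CI_high", "p_value"]

    def test_no_survivor_gives_prevalence_model(self, rng):
        n = 40
        y = np.r_[np.zeros(30, int), np.ones(10, int)]
        clin = pd.DataFrame({"age": np.full(n, 50.0)})
        with pytest.warns(UserWarning):
            model, _ = fit_clinical_model(clin, y)
        p = predict_prob(model, pd.DataFrame({"age": [50.0, 60.0]}))
        np.testing.assert_allclose(p, 0.25, atol=1e-9)


class TestCombinedModel:
    def test_strong_candidate_enters_first(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        cand = {
            "strong": y + 0.2 * rng.normal(size=n),
            "weak": rng.normal(size=n),
        }
        model = fit_combined_model(cand, y)
        assert model.feature_names[0] == "strong"

    def test_pure_noise_mostly_empty(self):
        empties = 0
        for trial in range(9):
            r = np.random.default_rng(trial)
            n = 200
            y = r.integers(0, 2, n)
            cand = {f"n{i}": r.normal(size=n) for i in range(3)}
            with np.errstate(all="ignore"):
                import warnings as w
                with w.catch_warnings():
                    w.simplefilter("ignore")
                    model = fit_combined_model(cand, y)
            empties += len(model.feature_names) == 0
        assert empties >= 5  # majority of replicates at alpha 0.05

    def test_matches_exhaustive_best_subset_on_strong_toy(self, rng):
        n = 150
        y = rng.integers(0, 2, n)
        cand = {
            "a": 2.0 * y + rng.normal(size=n),
            "b": 1.0 * y + rng.normal(size=n),
            "c": rng.normal(size=n),
        }
        model = fit_combined_model(cand, y)
        chosen = set(model.feature_names)
        # exhaustive subset search by BIC-free LRT chain admits exactly {a, b}
        assert chosen == {"a", "b"}

    def test_entry_alpha_default(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        model = fit_combined_model({"x": y + rng.normal(0, 0.5, n)}, y)
        assert model.hyperparameters["entry_alpha"] == 0.05


class TestPredictProb:
    def test_monotone_in_positive_coefficient(self):
        model = TrainedModel("logistic", {}, ["f"], np.array([0.0]), np.array([1.0]),
                             coef=np.array([2.0]), intercept=0.0)
        x = pd.DataFrame({"f": np.linspace(-3, 3, 20)})
        p = predict_prob(model, x)
        assert (np.diff(p) > 0).all()

    def test_schema_mismatch_named(self):
        model = TrainedModel("logistic", {}, ["f"], np.array([0.0]), np.array([1.0]),
                             coef=np.array([1.0]))
        with pytest.raises(ValueError, match="f"):
            predict_prob(model, pd.DataFrame({"g": [1.0]}))


def test_encode_clinical_one_hot_and_impute():
    clin = pd.DataFrame({
        "age": [50.0, np.nan, 60.0, 55.0, 52.0],
        "diameter": [20.0, 25.0, np.nan, 30.0, 22.0],
        "location": [1, 2, 3, 4, 2],
        "laterality": [0, 1, 0, 1, 0],
        "birads": [3, 4, 5, 4, np.nan],
    })
    enc = encode_clinical(clin)
    assert enc.notna().all().all()
    assert {"location_q2", "location_q3", "location_q4"} <= set(enc.columns)
    assert "location_q1" not in enc.columns  # reference level
    assert enc.loc[1, "age"] == pytest.approx(clin["age"].median())
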