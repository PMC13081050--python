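"""Signature, clinical, and combined models.

Five signature models (clinical, whole-tumor radiomics, each peritumoral
ring, habitat) are trained with grid search over stratified 5-fold CV AUC;
margin-based classifiers get a Platt probability calibration fit on
out-of-fold margins.  The combined model integrates the habitat score, the
1 mm peritumoral score and the screened clinical covariates by forward
stepwise logistic regression with likelihood-ratio entry tests at p < 0.05.
All scaling/calibration statistics are frozen from the training cohort.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "CohortSplit",
    "TrainedModel",
    "stratified_split",
    "fit_signature_model",
    "fit_clinical_model",
    "fit_combined_model",
    "predict_prob",
    "DEFAULT_GRIDS",
]

SUPPORTED_ALGORITHMS = ("logistic", "linear-SVM", "extra-trees", "stepwise-logistic")

DEFAULT_GRIDS = {
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "linear-SVM": {"C": [0.01, 0.1, 1.0, 10.0]},
    "extra-trees": {"n_estimators": [100, 300], "max_depth": [3, 5, None]},
}


@dataclass
class CohortSplit:
    train_ids: list
    validation_ids: list
    stratify_on: str
    ratio: float
    seed: int


def stratified_split(case_ids, labels, ratio: float = 0.7, seed: int = 0,
                     stratify_on: str = "label") -> CohortSplit:
    """Stratified train/validation split by largest-remainder allocation.

    Per-class training counts are ``round_lr(ratio * n_class)`` so each
    part's class proportions are within one case of the overall proportion.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = np.asarray(case_ids)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need at least 2 cases per class")
    # largest-remainder rounding of per-class train counts to the global total
    exact = counts * ratio
    base = np.floor(exact).astype(int)
    total = int(np.floor(exact.sum() + 0.5))
    rem_order = np.argsort(-(exact - base), kind="stable")
    for i in range(total - base.sum()):
        base[rem_order[i % len(base)]] += 1
    rng = np.random.default_rng(seed)
    train_ids, val_ids = [], []
    for cls, n_train in zip(classes, base):
        members = ids[y == cls]
        perm = rng.permutation(len(members))
        train_ids.extend(members[perm[:n_train]].tolist())
        val_ids.extend(members[perm[n_train:]].tolist())
    return CohortSplit(train_ids, val_ids, stratify_on, ratio, seed)


@dataclass
class TrainedModel:
    algorithm: str
    hyperparameters: dict
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    coef: np.ndarray | None = None          # linear algorithms
    intercept: float = 0.0
    calibration: tuple[float, float] | None = None  # Platt (slope, offset) on margins
    tree_model: object | None = None        # extra-trees estimator
    selected_terms: list[dict] = field(default_factory=list)  # stepwise entries
    cv_auc: float | None = None
    seed: int = 0

    def save(self, path: str) -> None:
        meta = {
            "algorithm": self.algorithm,
            "hyperparameters": self.hyperparameters,
            "feature_names": self.feature_names,
            "feature_means": np.asarray(self.feature_means).tolist(),
            "feature_sds": np.asarray(self.feature_sds).tolist(),
            "coef": None if self.coef is None else np.asarray(self.coef).tolist(),
            "intercept": self.intercept,
            "calibration": self.calibration,
            "selected_terms": self.selected_terms,
            "cv_auc": self.cv_auc,
            "seed": self.seed,
            "version": "1.0",
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)
        if self.tree_model is not None:
            joblib.dump(self.tree_model, path + ".trees")

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(path) as fh:
            meta = json.load(fh)
        meta.pop("version", None)
        meta["feature_means"] = np.asarray(meta["feature_means"])
        meta["feature_sds"] = np.asarray(meta["feature_sds"])
        if meta["coef"] is not None:
            meta["coef"] = np.asarray(meta["coef"])
        if meta["calibration"] is not None:
            meta["calibration"] = tuple(meta["calibration"])
        model = cls(**meta)
        try:
            model.tree_model = joblib.load(path + ".trees")
        except FileNotFoundError:
            pass
        return model


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    if isinstance(features, pd.Series):
        return features.to_frame()
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"f{i}" for i in range(arr.shape[1])])


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if algorithm == "linear-SVM":
        return LinearSVC(random_state=seed, max_iter=20000, **params)
    if algorithm == "extra-trees":
        return ExtraTreesClassifier(random_state=seed, **params)
    raise ValueError(f"unsupported algorithm: {algorithm}")


def _complexity(algorithm: str, params: dict) -> tuple:
    if algorithm in ("logistic", "linear-SVM"):
        return (params["C"],)  # larger C = weaker regularization = more complex
    if algorithm == "extra-trees":
        depth = params.get("max_depth")
        return (params.get("n_estimators", 0), np.inf if depth is None else depth)
    return ()


def _platt(margins: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Monotone sigmoid calibration: p = sigmoid(a*margin + b), fit by
    unpenalized logistic regression on out-of-fold margins."""
    lr = LogisticRegression(C=1e6, max_iter=2000)
    lr.fit(margins[:, None], y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def fit_signature_model(
    features,
    labels,
    algorithm: str = "linear-SVM",
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Grid search over mean stratified ``folds``-fold CV AUC, refit on all
    training rows; ties prefer the smallest-complexity grid point, then grid
    order.  Linear-SVM margins are mapped to probabilities with a Platt
    sigmoid fit on out-of-fold margins at the winning grid point."""
    table = _as_frame(features)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    if table.isna().any().any():
        raise ValueError("missing values: impute first")
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    keys = list(grid)
    points = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
    if not points:
        raise ValueError("empty hyperparameter grid")

    Z, mu, sd = _standardize(table.to_numpy(dtype=float))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))

    results = []
    for order, params in enumerate(points):
        aucs = []
        for tr, te in splits:
            est = _make_estimator(algorithm, params, seed)
            est.fit(Z[tr], y[tr])
            score = (est.decision_function(Z[te]) if hasattr(est, "decision_function")
                     else est.predict_proba(Z[te])[:, 1])
            aucs.append(roc_auc_score(y[te], score))
        results.append((float(np.mean(aucs)), params, order))
    best_auc = max(r[0] for r in results)
    winners = [r for r in results if r[0] == best_auc]
    winners.sort(key=lambda r: (_complexity(algorithm, r[1]), r[2]))
    _, best_params, _ = winners[0]

    est = _make_estimator(algorithm, best_params, seed)
    est.fit(Z, y)
    model = TrainedModel(
        algorithm=algorithm,
        hyperparameters=best_params,
        feature_names=list(table.columns),
        feature_means=mu,
        feature_sds=sd,
        cv_auc=best_auc,
        seed=seed,
    )
    if algorithm in ("logistic", "linear-SVM"):
        model.coef = est.coef_[0].astype(float)
        model.intercept = float(est.intercept_[0])
        if algorithm == "linear-SVM":
            oof_m = np.empty(len(y))
            for tr, te in splits:
                e = _make_estimator(algorithm, best_params, seed)
                e.fit(Z[tr], y[tr])
                oof_m[te] = e.decision_function(Z[te])
            model.calibration = _platt(oof_m, y)
    else:
        model.tree_model = est
    return model


def _score_test_p(x: np.ndarray, y: np.ndarray) -> float:
    """Rao score test for a logistic slope (closed form, defined even under
    perfect separation)."""
    ybar = y.mean()
    u = float((x * (y - ybar)).sum())
    var = ybar * (1 - ybar) * float(((x - x.mean()) ** 2).sum())
    if var <= 0:
        return 1.0
    from scipy.stats import norm
    return float(2.0 * norm.sf(abs(u) / np.sqrt(var)))


def _univariate_logistic(x: np.ndarray, y: np.ndarray):
    """Single-covariate logistic fit; returns (OR, CI low, CI high, p).

    Under separation/divergence the ML fit fails; the p-value then comes
    from the score test and the OR from a weakly ridge-penalized fit."""
    X = sm.add_constant(x.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0)
        beta, se = res.params[1], res.bse[1]
        if np.isfinite(se) and abs(beta) < 50:
            # LRT p rather than Wald: the Wald test collapses near
            # separation (Hauck-Donner), silently discarding the strongest
            # covariates
            from scipy.stats import chi2
            p = float(chi2.sf(2.0 * (res.llf - res.llnull), 1))
            return (float(np.exp(beta)), float(np.exp(beta - 1.96 * se)),
                    float(np.exp(beta + 1.96 * se)), p)
    except Exception:
        pass
    clf = LogisticRegression(C=100.0, max_iter=5000)
    clf.fit(x[:, None].astype(float), y)
    return float(np.exp(clf.coef_[0, 0])), np.nan, np.nan, _score_test_p(x, y)


_CATEGORICAL_COVARIATES = {"location", "laterality", "birads"}


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Impute (median for numerics, mode for categoricals) and encode:
    BI-RADS ordinal, quadrant location one-hot (reference = quadrant 1),
    laterality binary."""
    df = clinical.copy()
    for col in df.columns:
        if df[col].isna().any():
            if col in _CATEGORICAL_COVARIATES or not pd.api.types.is_numeric_dtype(df[col]):
                df[col] = df[col].fillna(df[col].mode().iloc[0])
            else:
                df[col] = df[col].fillna(df[col].median())
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        if col == "location":
            for q in sorted(df[col].unique())[1:]:
                out[f"location_q{int(q)}"] = (df[col] == q).astype(float)
        else:
            out[col] = df[col].astype(float)
    return out


def fit_clinical_model(clinical: pd.DataFrame, labels, alpha: float = 0.05,
                       seed: int = 0) -> tuple[TrainedModel, pd.DataFrame]:
    """Univariate logistic screen per covariate (OR / 95% CI / p); covariates
    with p < alpha enter a ridge-regularized logistic model.  Returns the
    model and the screening report."""
    y = np.asarray(labels).astype(int)
    enc = encode_clinical(clinical.drop(columns=[c for c in ("label",) if c in clinical]))
    rows = []
    passed = []
    for col in enc.columns:
        x = enc[col].to_numpy()
        if np.ptp(x) == 0:
            rows.append({"variable": col, "OR": np.nan, "CI_low": np.nan,
                         "CI_high": np.nan, "p_value": 1.0})
            continue
        orr, lo, hi, p = _univariate_logistic(x, y)
        rows.append({"variable": col, "OR": orr, "CI_low": lo, "CI_high": hi, "p_value": p})
        if p < alpha:
            passed.append(col)
    report = pd.DataFrame(rows).set_index("variable")
    if not passed:
        warnings.warn("no clinical covariate passed the univariate screen: intercept-only model")
        prev = y.mean()
        model = TrainedModel("logistic", {"C": 1.0}, [], np.zeros(0), np.ones(0),
                             coef=np.zeros(0), intercept=float(np.log(prev / (1 - prev))),
                             seed=seed)
        return model, report
    Z, mu, sd = _standardize(enc[passed].to_numpy(dtype=float))
    clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    clf.fit(Z, y)
    model = TrainedModel("logistic", {"C": 1.0}, passed, mu, sd,
                         coef=clf.coef_[0].astype(float),
                         intercept=float(clf.intercept_[0]), seed=seed)
    return model, report


def _fit_logit_loglik(X: np.ndarray, y: np.ndarray):
    """ML logistic fit returning (params, loglik); ridge fallback on
    separation/divergence (flagged with a warning)."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 50:
            return np.asarray(res.params), float(res.llf)
    except Exception:
        pass
    warnings.warn("separation detected: weakly ridge-penalized logistic fallback")
    clf = LogisticRegression(C=100.0, max_iter=5000)
    if X.shape[1] == 0:
        prev = np.clip(y.mean(), 1e-9, 1 - 1e-9)
        params = np.array([np.log(prev / (1 - prev))])
        eta = np.full(len(y), params[0])
    else:
        clf.fit(X, y)
        params = np.concatenate([clf.intercept_, clf.coef_[0]])
        eta = params[0] + X @ params[1:]
    p = np.clip(1 / (1 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return params, float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def fit_combined_model(candidates: dict[str, np.ndarray | pd.Series], labels,
                       entry_alpha: float = 0.05, seed: int = 0) -> TrainedModel:
    """Forward stepwise logistic regression with likelihood-ratio entry tests.

    At each step the candidate with the smallest LRT p-value enters if
    p < ``entry_alpha``; there is no removal step.  Entry order, per-term
    coefficients and entry p-values are recorded."""
    y = np.asarray(labels).astype(int)
    names = list(candidates)
    cols = {k: np.asarray(v, dtype=float).ravel() for k, v in candidates.items()}
    n = len(y)
    for k, v in cols.items():
        if len(v) != n:
            raise ValueError(f"candidate '{k}' not aligned to cases")
        if np.isnan(v).any():
            raise ValueError(f"candidate '{k}' has missing values")
    mu = {k: v.mean() for k, v in cols.items()}
    sd = {k: (v.std() if v.std() > 0 else 1.0) for k, v in cols.items()}
    z = {k: (v - mu[k]) / sd[k] for k, v in cols.items()}

    selected: list[str] = []
    terms: list[dict] = []
    _, ll_cur = _fit_logit_loglik(np.empty((n, 0)), y)
    while True:
        remaining = [c for c in names if c not in selected]
        if not remaining:
            break
        best = None
        for cand in remaining:
            X = np.column_stack([z[c] for c in selected + [cand]])
            params, ll = _fit_logit_loglik(X, y)
            lrt = 2.0 * (ll - ll_cur)
            from scipy.stats import chi2
            p = float(chi2.sf(max(lrt, 0.0), df=1))
            if best is None or p < best[0]:
                best = (p, cand, ll, params)
        p, cand, ll, params = best
        if p >= entry_alpha:
            break
        selected.append(cand)
        ll_cur = ll
        terms.append({"term": cand, "entry_p": p})
    if not selected:
        warnings.warn("no candidate entered the combined model: intercept-only")
        prev = np.clip(y.mean(), 1e-9, 1 - 1e-9)
        return TrainedModel("stepwise-logistic", {"entry_alpha": entry_alpha}, [],
                            np.zeros(0), np.ones(0), coef=np.zeros(0),
                            intercept=float(np.log(prev / (1 - prev))), seed=seed)
    X = np.column_stack([z[c] for c in selected])
    params, _ = _fit_logit_loglik(X, y)
    for i, t in enumerate(terms):
        t["coef"] = float(params[1 + i])
    return TrainedModel(
        "stepwise-logistic", {"entry_alpha": entry_alpha}, selected,
        np.array([mu[c] for c in selected]), np.array([sd[c] for c in selected]),
        coef=np.asarray(params[1:], dtype=float), intercept=float(params[0]),
        selected_terms=terms, seed=seed,
    )


def predict_prob(model: TrainedModel, features) -> np.ndarray:
    """Probability predictions with frozen scaling and calibration."""
    table = _as_frame(features)
    if model.feature_names:
        missing = [c for c in model.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        X = table[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.empty((len(table), 0))
    Z = (X - model.feature_means) / model.feature_sds if X.shape[1] else X
    if model.algorithm == "extra-trees":
        return model.tree_model.predict_proba(Z)[:, 1]
    eta = model.intercept + (Z @ model.coef if Z.shape[1] else np.zeros(len(table)))
    if model.algorithm == "linear-SVM" and model.calibration is not None:
        a, b = model.calibration
        eta = a * eta + b
    return 1.0 / (1.0 + np.exp(-eta))
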