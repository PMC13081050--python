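"""Four-stage feature-selection cascade and Rad-score construction.

Stages (strictly nested survivors): Mann-Whitney univariate filter at
alpha 0.05 -> iterative Pearson-correlation pruning at |r| > 0.9 -> mRMR
ranking keeping the top 32 -> L1-penalized logistic regression with 10-fold
cross-validated penalty choice.  The Rad-score is the resulting linear
predictor over training-standardized features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionReport",
    "univariate_filter",
    "correlation_prune",
    "mrmr_rank",
    "lasso_select",
    "rad_score",
    "run_cascade",
]


@dataclass
class SelectionReport:
    stage_survivors: dict[str, list[str]]
    coefficients: dict[str, float]
    intercept: float
    lasso_lambda: float
    cv_curve: dict[float, float]  # lambda -> mean CV error
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    seed: int
    correlation_threshold: float = 0.9
    mrmr_top: int = 32
    cv_metric: str = "deviance"
    warnings_: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        obj = {k: getattr(self, k) for k in (
            "stage_survivors", "coefficients", "intercept", "lasso_lambda",
            "feature_means", "feature_sds", "seed", "correlation_threshold",
            "mrmr_top", "cv_metric", "warnings_")}
        obj["cv_curve"] = {str(k): v for k, v in self.cv_curve.items()}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SelectionReport":
        with open(path) as fh:
            o = json.load(fh)
        o["cv_curve"] = {float(k): v for k, v in o["cv_curve"].items()}
        return cls(**o)


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    return y


def univariate_filter(table: pd.DataFrame, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Keep features whose two-sided Mann-Whitney U p-value is below alpha."""
    y = _check_labels(labels)
    if table.isna().any().any():
        raise ValueError("impute missing values before selection")
    g0 = table.loc[y == 0]
    g1 = table.loc[y == 1]
    keep = []
    for col in table.columns:
        a, b = g1[col].to_numpy(), g0[col].to_numpy()
        if np.ptp(table[col].to_numpy()) == 0:
            continue  # constant feature: no association (p = 1)
        p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        if p < alpha:
            keep.append(col)
    return table[keep]


def correlation_prune(table: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Iteratively drop the feature with the most |r| > threshold partners.

    Ties are broken by larger mean absolute correlation, then lexicographic
    feature name, so the outcome is deterministic and order-independent.
    Zero-variance features correlate with nothing and survive this stage.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    cols = list(table.columns)
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0  # zero-variance pairs
    np.fill_diagonal(corr, 0.0)
    absc = np.abs(corr)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        over = (absc > threshold) & alive[None, :] & alive[:, None]
        degree = over.sum(axis=1)
        if degree.max(initial=0) == 0:
            break
        cand = np.flatnonzero(degree == degree.max())
        mean_abs = np.where(alive, absc, 0.0)[np.ix_(cand, alive)].mean(axis=1)
        best = cand[np.lexsort((np.array(cols, dtype=object)[cand], -mean_abs))][0]
        alive[best] = False
    del sd
    return table[[c for c, a in zip(cols, alive) if a]]


def _quartile_discretize(x: np.ndarray) -> np.ndarray:
    qs = np.quantile(x, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, x, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) between two small-alphabet integer vectors."""
    ja, ia = np.unique(a, return_inverse=True)
    jb, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((len(ja), len(jb)))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(table: pd.DataFrame, labels, m: int = 32) -> pd.DataFrame:
    """Greedy mRMR (mutual-information difference) after quartile
    discretization; returns the first min(m, available) features in
    selection order."""
    y = _check_labels(labels)
    cols = list(table.columns)
    disc = {c: _quartile_discretize(table[c].to_numpy(dtype=float)) for c in cols}
    relevance = {c: _mutual_information(disc[c], y) for c in cols}
    selected: list[str] = []
    redundancy = {c: 0.0 for c in cols}
    while cols and len(selected) < m:
        if selected:
            score = {c: relevance[c] - redundancy[c] / len(selected) for c in cols}
        else:
            score = relevance
        best = max(cols, key=lambda c: (score[c], c))
        selected.append(best)
        cols.remove(best)
        for c in cols:
            redundancy[c] += _mutual_information(disc[c], disc[best])
    return table[selected]


def lasso_select(
    table: pd.DataFrame,
    labels,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 40,
    cv_metric: str = "deviance",
    correlation_threshold: float = 0.9,
    mrmr_top: int = 32,
    stage_survivors: dict[str, list[str]] | None = None,
) -> SelectionReport:
    """L1-penalized logistic path with stratified ``folds``-fold CV.

    The penalty minimizing the mean CV error (binomial deviance by default;
    ``cv_metric='mse'`` mirrors the squared-error curve convention) is
    selected and the model refit on all rows; nonzero coefficients define
    the Rad-score.  Coefficients are reported on the z-scored feature scale
    with the scaling statistics frozen for test-time reuse.
    """
    y = _check_labels(labels)
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        raise ValueError(f"need at least {folds} cases per class")
    if table.shape[1] == 0:
        warnings.warn("no candidate features reached the LASSO stage")
        prev = y.mean()
        return SelectionReport(
            stage_survivors=dict(stage_survivors or {}, lasso=[]),
            coefficients={}, intercept=float(np.log(prev / (1 - prev))),
            lasso_lambda=np.inf, cv_curve={}, feature_means={}, feature_sds={},
            seed=seed, correlation_threshold=correlation_threshold,
            mrmr_top=mrmr_top, cv_metric=cv_metric,
            warnings_=["empty candidate set"],
        )
    X = table.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe
    n = len(y)

    # lambda grid: log-spaced below the smallest penalty that kills every
    # coefficient (lambda_max = max |X^T (y - ybar)| / n for logistic)
    lam_max = np.abs(Z.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    lambdas = np.logspace(np.log10(lam_max * 1.05), np.log10(lam_max * 1e-3), n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))
    cv_err = np.zeros(n_lambdas)
    for tr, te in splits:
        for i, lam in enumerate(lambdas):
            C = 1.0 / (n * lam)
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", random_state=seed)
            clf.fit(Z[tr], y[tr])
            p = np.clip(clf.predict_proba(Z[te])[:, 1], 1e-12, 1 - 1e-12)
            if cv_metric == "mse":
                cv_err[i] += ((p - y[te]) ** 2).sum()
            else:
                cv_err[i] += -(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)).sum()
    cv_err /= n
    best = int(np.argmin(cv_err))
    lam = float(lambdas[best])
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", random_state=seed)
    clf.fit(Z, y)
    coefs = {c: float(w) for c, w in zip(table.columns, clf.coef_[0]) if w != 0.0}
    warns = []
    if not coefs:
        warnings.warn("no penalty yielded nonzero coefficients")
        warns.append("empty coefficient set")
    survivors = dict(stage_survivors or {})
    survivors["lasso"] = list(coefs)
    return SelectionReport(
        stage_survivors=survivors,
        coefficients=coefs,
        intercept=float(clf.intercept_[0]),
        lasso_lambda=lam,
        cv_curve={float(l): float(e) for l, e in zip(lambdas, cv_err)},
        feature_means={c: float(m) for c, m in zip(table.columns, mu)},
        feature_sds={c: float(s) for c, s in zip(table.columns, sd_safe)},
        seed=seed,
        correlation_threshold=correlation_threshold,
        mrmr_top=mrmr_top,
        cv_metric=cv_metric,
        warnings_=warns,
    )


def rad_score(report: SelectionReport, table: pd.DataFrame) -> pd.Series:
    """Linear predictor: intercept + sum of coef_j x standardized feature_j."""
    missing = [c for c in report.coefficients if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    score = np.full(len(table), report.intercept)
    for c, w in report.coefficients.items():
        z = (table[c].to_numpy(dtype=float) - report.feature_means[c]) / report.feature_sds[c]
        score = score + w * z
    return pd.Series(score, index=table.index, name="rad_score")


def run_cascade(
    table: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    correlation_threshold: float = 0.9,
    mrmr_top: int = 32,
    folds: int = 10,
    seed: int = 0,
    cv_metric: str = "deviance",
) -> SelectionReport:
    """Run all four stages in order and return the full report."""
    stage1 = univariate_filter(table, labels, alpha=alpha)
    stage2 = correlation_prune(stage1, threshold=correlation_threshold)
    stage3 = mrmr_rank(stage2, labels, m=mrmr_top)
    survivors = {
        "univariate": list(stage1.columns),
        "correlation": list(stage2.columns),
        "mrmr": list(stage3.columns),
    }
    return lasso_select(
        stage3, labels, folds=folds, seed=seed, cv_metric=cv_metric,
        correlation_threshold=correlation_threshold, mrmr_top=mrmr_top,
        stage_survivors=survivors,
    )
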