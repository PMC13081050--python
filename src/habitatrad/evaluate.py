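"""Discrimination, calibration, clinical-utility, comparison and
explanation statistics.

AUC confidence intervals and paired model comparisons use DeLong's
structural-components method; calibration is the Hosmer-Lemeshow grouped
chi-square; clinical utility is decision-curve net benefit; attributions are
Shapley values (closed form for linear models, kernel-weighted coalition
regression for tree models); the combined model is summarized as a nomogram
points table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import TrainedModel, predict_prob

__all__ = [
    "auc_delong",
    "delong_paired",
    "classification_metrics",
    "youden_threshold",
    "hosmer_lemeshow",
    "net_benefit",
    "shap_attributions",
    "nomogram_points",
    "case_total_points",
    "EvaluationReport",
    "evaluate_cohort",
]


# ---------------------------------------------------------------------------
# DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(probs: np.ndarray, labels: np.ndarray):
    y = np.asarray(labels).astype(int)
    pos = np.asarray(probs, dtype=float)[y == 1]
    neg = np.asarray(probs, dtype=float)[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("labels must contain both classes")
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # per-positive structural components
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # per-negative
    return auc, v10, v01


def auc_delong(probs, labels, alpha: float = 0.95) -> tuple[float, float, float]:
    """AUC (Mann-Whitney with ties counted 1/2) and its DeLong CI,
    clipped to [0, 1]."""
    auc, v10, v01 = _delong_components(np.asarray(probs), np.asarray(labels))
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    zq = sps.norm.ppf(0.5 + alpha / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def delong_paired(probsA, probsB, labels) -> float:
    """Two-sided p for the paired DeLong test of AUC_A = AUC_B.

    Identical score vectors have zero difference and zero variance; p is
    defined as 1 in that case."""
    pa, pb = np.asarray(probsA, dtype=float), np.asarray(probsB, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("probability vectors must cover the same cases")
    aucA, v10A, v01A = _delong_components(pa, labels)
    aucB, v10B, v01B = _delong_components(pb, labels)
    m, n = len(v10A), len(v01A)
    s10 = np.cov(np.stack([v10A, v10B]), ddof=1)
    s01 = np.cov(np.stack([v01A, v01B]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucA - aucB
    if var <= 0:
        return 1.0 if np.isclose(diff, 0.0) else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Threshold metrics


def youden_threshold(probs, labels) -> float:
    """Probability cut maximizing sensitivity + specificity - 1."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    cuts = np.unique(p)
    best_t, best_j = cuts[0], -np.inf
    for t in cuts:
        pred = p >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def classification_metrics(probs, labels, threshold: float) -> dict[str, float]:
    """Confusion-matrix metrics at ``prob >= threshold``.  Ratios with an
    empty denominator are reported as NaN (undefined), never 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = p >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())

    def ratio(a, b):
        return a / b if b > 0 else np.nan

    return {
        "threshold": float(threshold),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow


def hosmer_lemeshow(probs, labels, groups: int = 10) -> tuple[float, float]:
    """Grouped chi-square calibration test on predicted-probability
    quantile bins; p from chi-square with ``groups - 2`` df.  Empty bins are
    merged with their neighbour (df adjusted, warning)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(p) < 2 * groups:
        raise ValueError("need at least 2 cases per group")
    edges = np.quantile(p, np.linspace(0, 1, groups + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < groups:
        warnings.warn("tied probability quantiles: bins merged, df adjusted")
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    stat = 0.0
    g_used = 0
    for g in range(len(edges) - 1):
        sel = idx == g
        ng = int(sel.sum())
        if ng == 0:
            continue
        obs = y[sel].sum()
        exp = p[sel].sum()
        denom = exp * (1.0 - exp / ng)
        if denom <= 0:
            denom = max(exp, 1e-10)
        stat += (obs - exp) ** 2 / denom
        g_used += 1
    df = max(g_used - 2, 1)
    return float(stat), float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Decision curves


def net_benefit(probs, labels, thresholds=None) -> pd.DataFrame:
    """Decision-curve net benefit NB(t) = TP/N - FP/N * t/(1-t) for the
    model, treat-all and treat-none policies over the threshold grid
    (default 0.01..0.80 step 0.01)."""
    t = np.asarray(thresholds, dtype=float) if thresholds is not None else np.arange(0.01, 0.801, 0.01)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must be in (0, 1)")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    N = len(y)
    prev = y.mean()
    rows = []
    for ti in t:
        pred = p >= ti
        tp = (pred & (y == 1)).sum() / N
        fp = (pred & (y == 0)).sum() / N
        odds = ti / (1.0 - ti)
        rows.append({
            "threshold": float(ti),
            "model": float(tp - fp * odds),
            "treat_all": float(prev - (1.0 - prev) * odds),
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SHAP attributions


def _model_output(model: TrainedModel, Z: np.ndarray) -> np.ndarray:
    """Model output on the attribution scale: linear predictor (with Platt
    calibration applied) for linear models, predicted probability for
    trees.  ``Z`` is standardized."""
    if model.algorithm == "extra-trees":
        return model.tree_model.predict_proba(Z)[:, 1]
    eta = model.intercept + Z @ model.coef
    if model.algorithm == "linear-SVM" and model.calibration is not None:
        a, b = model.calibration
        eta = a * eta + b
    return eta


def _kernel_shap_case(f, x: np.ndarray, bg: np.ndarray, rng: np.random.Generator,
                      n_coalitions: int = 2048) -> np.ndarray:
    """KernelSHAP for one case: weighted least squares over sampled
    coalitions with the additivity constraint enforced exactly."""
    M = len(x)
    fx = float(f(x[None, :])[0])
    f0 = float(f(bg).mean())
    if M == 1:
        return np.array([fx - f0])
    sizes = np.arange(1, M)
    w_sizes = (M - 1) / (sizes * (M - sizes))
    w_sizes /= w_sizes.sum()
    n_samp = min(n_coalitions, 2 ** M - 2)
    Zs, vals, ws = [], [], []
    seen = set()
    for _ in range(n_samp):
        k = rng.choice(sizes, p=w_sizes)
        members = tuple(sorted(rng.choice(M, size=k, replace=False)))
        if members in seen:
            continue
        seen.add(members)
        z = np.zeros(M)
        z[list(members)] = 1.0
        # value: expectation over background of f with coalition features fixed
        rep = np.tile(bg, (1, 1)).copy()
        rep[:, list(members)] = x[list(members)]
        Zs.append(z)
        vals.append(float(f(rep).mean()))
        ws.append((M - 1) / (len(members) * (M - len(members))))
    Zm = np.asarray(Zs)
    v = np.asarray(vals) - f0
    W = np.asarray(ws)
    # solve min ||W^(1/2)(Z phi - v)|| s.t. sum(phi) = fx - f0
    A = Zm * np.sqrt(W)[:, None]
    b = v * np.sqrt(W)
    lhs = np.block([[A.T @ A, np.ones((M, 1))], [np.ones((1, M)), np.zeros((1, 1))]])
    rhs = np.concatenate([A.T @ b, [fx - f0]])
    sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    return sol[:M]


def shap_attributions(
    model: TrainedModel,
    background: pd.DataFrame,
    cases: pd.DataFrame,
    seed: int = 0,
    n_coalitions: int = 2048,
) -> tuple[np.ndarray, float]:
    """Per-case additive attributions and the background base value.

    Linear models use the exact closed form phi_j = w_j (z_j - mean(z_j^bg))
    on the linear-predictor scale; tree models use kernel-weighted coalition
    sampling (fixed seed) on the probability scale.  Every row satisfies
    base_value + sum(attributions) = model output.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    fn = model.feature_names
    Zb = (background[fn].to_numpy(dtype=float) - model.feature_means) / model.feature_sds
    Zc = (cases[fn].to_numpy(dtype=float) - model.feature_means) / model.feature_sds
    if model.algorithm in ("logistic", "linear-SVM", "stepwise-logistic"):
        w = model.coef.astype(float).copy()
        if model.algorithm == "linear-SVM" and model.calibration is not None:
            w = w * model.calibration[0]
        base = float(_model_output(model, Zb).mean())
        attr = (Zc - Zb.mean(axis=0)) * w[None, :]
        return attr, base
    rng = np.random.default_rng(seed)
    f = lambda Z: _model_output(model, Z)
    base = float(f(Zb).mean())
    attr = np.stack([_kernel_shap_case(f, z, Zb, rng, n_coalitions) for z in Zc])
    return attr, base


# ---------------------------------------------------------------------------
# Nomogram


def nomogram_points(model: TrainedModel, variable_ranges: dict[str, tuple[float, float]],
                    n_lookup: int = 50) -> dict:
    """Points table for a linear-in-terms logistic model.

    Each term's contribution range |coef x (range width on the standardized
    scale)| is computed; the largest maps to 0-100 points and the others
    scale proportionally.  A total-points -> probability lookup consistent
    with ``predict_prob`` is included."""
    if model.coef is None:
        raise ValueError("nomogram requires a linear-in-terms logistic model")
    terms = []
    contribs = []
    for name, w, mu, sd in zip(model.feature_names, model.coef,
                               model.feature_means, model.feature_sds):
        lo, hi = variable_ranges[name]
        width = (hi - lo) / sd
        contrib = abs(w) * width
        if contrib == 0:
            warnings.warn(f"term '{name}' has zero contribution range: 0 points")
        contribs.append(contrib)
        terms.append({"term": name, "coef": float(w), "lo": float(lo), "hi": float(hi)})
    max_contrib = max(contribs) if contribs else 0.0
    if max_contrib == 0:
        raise ValueError("all terms have zero contribution range")
    unit = max_contrib / 100.0  # log-odds per point
    base_eta = model.intercept
    for t, contrib in zip(terms, contribs):
        w, lo, hi = t["coef"], t["lo"], t["hi"]
        mu = model.feature_means[model.feature_names.index(t["term"])]
        sd = model.feature_sds[model.feature_names.index(t["term"])]
        ref = lo if w >= 0 else hi  # value contributing least
        t["points_max"] = contrib / unit
        t["sd"] = float(sd)
        t["ref_value"] = float(ref)
        base_eta += w * (ref - mu) / sd
    total_max = sum(t["points_max"] for t in terms)
    grid = np.linspace(0.0, total_max, n_lookup)
    lookup = pd.DataFrame({
        "total_points": grid,
        "probability": 1.0 / (1.0 + np.exp(-(base_eta + grid * unit))),
    })
    return {"terms": terms, "points_unit_logodds": unit, "base_eta": float(base_eta),
            "lookup": lookup}


def case_total_points(nomo: dict, case: dict[str, float]) -> float:
    """Total nomogram points for one case: each term contributes
    coef x (value - reference)/sd log-odds, expressed in point units."""
    total = 0.0
    for t in nomo["terms"]:
        contrib = t["coef"] * (case[t["term"]] - t["ref_value"]) / t["sd"]
        total += contrib / nomo["points_unit_logodds"]
    return float(total)


# ---------------------------------------------------------------------------
# Cohort report


@dataclass
class EvaluationReport:
    cohort: str
    auc: float
    ci: tuple[float, float]
    metrics: dict[str, float]
    hl_statistic: float
    hl_p: float
    dca: pd.DataFrame
    threshold: float
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        """Write the scalar report as JSON and the decision curve as a CSV
        next to it (same stem, ``_dca.csv`` suffix)."""
        import json

        def clean(v):
            return None if isinstance(v, float) and np.isnan(v) else v

        obj = {
            "cohort": self.cohort,
            "auc": self.auc,
            "ci": list(self.ci),
            "metrics": {k: clean(v) for k, v in self.metrics.items()},
            "hl_statistic": clean(self.hl_statistic),
            "hl_p": clean(self.hl_p),
            "threshold": self.threshold,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
        self.dca.to_csv(path.rsplit(".", 1)[0] + "_dca.csv", index=False)


def evaluate_cohort(probs, labels, cohort: str = "train",
                    threshold: float | None = None,
                    hl_groups: int = 10) -> EvaluationReport:
    """The full per-cohort battery: AUC with DeLong CI, threshold metrics at
    the (training-frozen) Youden threshold, Hosmer-Lemeshow calibration, and
    the decision curve."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    t = youden_threshold(probs, labels) if threshold is None else float(threshold)
    auc, lo, hi = auc_delong(probs, labels)
    try:
        hl_stat, hl_p = hosmer_lemeshow(probs, labels, groups=hl_groups)
    except ValueError:
        hl_stat, hl_p = np.nan, np.nan
    return EvaluationReport(
        cohort=cohort,
        auc=auc,
        ci=(lo, hi),
        metrics=classification_metrics(probs, labels, t),
        hl_statistic=hl_stat,
        hl_p=hl_p,
        dca=net_benefit(probs, labels),
        threshold=t,
    )
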