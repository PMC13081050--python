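import itertools

import numpy as np
import pandas as pd
import pytest

from habitatrad.selection import (
    correlation_prune,
    lasso_select,
    mrmr_rank,
    rad_score,
    run_cascade,
    univariate_filter,
)


class TestUnivariateFilter:
    def test_separated_feature_kept_exact_p(self):
        t = pd.DataFrame({"f": [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]}, dtype=float)
        y = [0] * 5 + [1] * 5
        # exact Mann-Whitney enumeration: p = 2/252 < 0.05
        kept = univariate_filter(t, y)
        assert list(kept.columns) == ["f"]

    def test_constant_feature_removed(self, rng):
        t = pd.DataFrame({"c": np.ones(20), "g": np.r_[np.zeros(10), np.ones(10)]})
        y = [0] * 10 + [1] * 10
        kept = univariate_filter(t, y)
        assert "c" not in kept.columns

    def test_alpha_one_keeps_everything(self, rng):
        t = pd.DataFrame(rng.normal(size=(20, 5)))
        y = rng.integers(0, 2, 20)
        y[:2], y[-2:] = 0, 1
        assert univariate_filter(t, y, alpha=1.0).shape[1] == 5

    def test_single_class_rejected(self, rng):
        t = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            univariate_filter(t, np.zeros(10))


def exhaustive_prune(table: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Independent re-implementation: repeatedly drop the max-degree feature
    (ties: larger mean |r|, then name)."""
    cols = list(table.columns)
    while True:
        corr = table[cols].corr().abs().fillna(0.0)
        np.fill_diagonal(corr.values, 0.0)
        deg = (corr > threshold).sum()
        if deg.max() == 0:
            return cols
        worst = deg.max()
        cand = [c for c in cols if deg[c] == worst]
        cand.sort(key=lambda c: (-corr.loc[c, cols].mean(), c))
        cols.remove(cand[0])


class TestCorrelationPrune:
    def test_uncorrelated_table_unchanged(self, rng):
        t = pd.DataFrame(rng.normal(size=(50, 6)))
        out = correlation_prune(t)
        assert list(out.columns) == list(t.columns)

    def test_hub_feature_removed_first(self, rng):
        n = 200
        base = rng.normal(size=n)
        a = rng.normal(size=n)
        f2 = base + 0.4 * a
        f3 = base - 0.4 * a
        f1 = f2 + f3 + 0.05 * rng.normal(size=n)  # hub: high |r| with both
        t = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
        corr = t.corr().abs()
        assert corr.loc["f1", "f2"] > 0.9 and corr.loc["f1", "f3"] > 0.9
        assert corr.loc["f2", "f3"] < 0.9
        out = correlation_prune(t)
        assert sorted(out.columns) == ["f2", "f3"]

    def test_matches_exhaustive_oracle_on_random_tables(self, rng):
        for trial in range(15):
            p = int(rng.integers(4, 13))
            latent = rng.normal(size=(40, max(2, p // 3)))
            mix = rng.normal(size=(latent.shape[1], p))
            X = latent @ mix + 0.1 * rng.normal(size=(40, p))
            t = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(p)])
            ours = list(correlation_prune(t).columns)
            assert ours == exhaustive_prune(t)

    def test_output_guarantee_max_corr(self, rng):
        latent = rng.normal(size=(60, 3))
        X = latent @ rng.normal(size=(3, 10)) + 0.05 * rng.normal(size=(60, 10))
        out = correlation_prune(pd.DataFrame(X))
        corr = out.corr().abs().values
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9


def brute_mrmr(table, y, m):
    """Step-by-step exhaustive evaluation of the MID criterion."""
    from habitatrad.selection import _mutual_information, _quartile_discretize
    disc = {c: _quartile_discretize(table[c].to_numpy()) for c in table.columns}
    y = np.asarray(y)
    selected = []
    remaining = list(table.columns)
    while remaining and len(selected) < m:
        best, best_score = None, -np.inf
        for c in sorted(remaining):
            rel = _mutual_information(disc[c], y)
            red = np.mean([_mutual_information(disc[c], disc[s]) for s in selected]) if selected else 0.0
            score = rel - red
            if score > best_score or (score == best_score and (best is None or c > best)):
                best, best_score = c, score
        selected.append(best)
        remaining.remove(best)
    return selected


class TestMrmr:
    def test_first_pick_is_max_relevance(self, rng):
        y = rng.integers(0, 2, 100)
        t = pd.DataFrame({
            "signal": y + 0.1 * rng.normal(size=100),
            "noise1": rng.normal(size=100),
            "noise2": rng.normal(size=100),
        })
        out = mrmr_rank(t, y, m=3)
        assert out.columns[0] == "signal"

    def test_redundant_copy_not_second(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        f1 = y + 0.05 * rng.normal(size=200)
        t = pd.DataFrame({
            "f1": f1,
            "f2": f1 + 1e-6 * rng.normal(size=200),  # near-copy of f1
            "f3": rng.normal(size=200),
            "f4": rng.normal(size=200),
        })
        out = mrmr_rank(t, y, m=4)
        first, second = out.columns[0], out.columns[1]
        assert first in ("f1", "f2")
        assert second not in ("f1", "f2")  # the redundant copy is demoted

    def test_top_m_retained(self, rng):
        t = pd.DataFrame(rng.normal(size=(60, 200)),
                         columns=[f"f{i}" for i in range(200)])
        y = rng.integers(0, 2, 60)
        y[:5], y[-5:] = 0, 1
        assert mrmr_rank(t, y, m=32).shape[1] == 32

    def test_matches_brute_force_on_small_tables(self, rng):
        for _ in range(10):
            p = int(rng.integers(3, 9))
            t = pd.DataFrame(rng.normal(size=(40, p)),
                             columns=[f"f{i}" for i in range(p)])
            y = rng.integers(0, 2, 40)
            y[0], y[-1] = 0, 1
            ours = list(mrmr_rank(t, y, m=p).columns)
            assert ours == brute_mrmr(t, y, p)


class TestLasso:
    def test_informative_feature_selected(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        t = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        t["f0"] = y * 2.0 + rng.normal(0, 0.5, n)
        report = lasso_select(t, y, seed=0)
        assert "f0" in report.coefficients

    def test_deterministic_under_seed(self, rng):
        n = 60
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        t = pd.DataFrame(rng.normal(size=(n, 5)))
        t.columns = [f"f{i}" for i in range(5)]
        a = lasso_select(t, y, seed=3)
        b = lasso_select(t, y, seed=3)
        assert a.coefficients == b.coefficients
        assert a.lasso_lambda == b.lasso_lambda

    def test_empty_candidate_set_handled(self):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        t = pd.DataFrame(index=range(40))
        with pytest.warns(UserWarning):
            report = lasso_select(t, y, folds=10)
        assert report.coefficients == {}
        assert report.intercept == pytest.approx(0.0)  # log-odds of 50% prevalence


class TestRadScore:
    def test_hand_arithmetic(self):
        from habitatrad.selection import SelectionReport
        report = SelectionReport(
            stage_survivors={}, coefficients={"f": 2.0}, intercept=-1.0,
            lasso_lambda=0.1, cv_curve={}, feature_means={"f": 0.0},
            feature_sds={"f": 1.0}, seed=0)
        t = pd.DataFrame({"f": [1.5]})
        assert rad_score(report, t).iloc[0] == pytest.approx(2.0)  # -1 + 2*1.5

    def test_invariant_to_extra_columns(self, rng):
        from habitatrad.selection import SelectionReport
        report = SelectionReport(
            stage_survivors={}, coefficients={"f": 1.0}, intercept=0.0,
            lasso_lambda=0.1, cv_curve={}, feature_means={"f": 2.0},
            feature_sds={"f": 3.0}, seed=0)
        t = pd.DataFrame({"f": rng.normal(size=8)})
        t2 = t.assign(junk=rng.normal(size=8))
        np.testing.assert_array_equal(rad_score(report, t), rad_score(report, t2))

    def test_missing_column_named(self):
        from habitatrad.selection import SelectionReport
        report = SelectionReport(
            stage_survivors={}, coefficients={"absent": 1.0}, intercept=0.0,
            lasso_lambda=0.1, cv_curve={}, feature_means={"absent": 0.0},
            feature_sds={"absent": 1.0}, seed=0)
        with pytest.raises(ValueError, match="absent"):
            rad_score(report, pd.DataFrame({"f": [1.0]}))


def test_cascade_nesting(rng):
    """Survivors are strictly nested across the four stages."""
    n = 80
    y = rng.integers(0, 2, n)
    latent = rng.normal(size=(n, 6))
    X = latent @ rng.normal(size=(6, 40)) + 0.3 * rng.normal(size=(n, 40))
    X[:, 0] += 2.0 * y
    X[:, 1] += 1.5 * y
    t = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(40)])
    report = run_cascade(t, y, seed=0)
    s = report.stage_survivors
    assert set(s["correlation"]) <= set(s["univariate"])
    assert set(s["mrmr"]) <= set(s["correlation"])
    assert set(s["lasso"]) <= set(s["mrmr"])
    assert set(report.coefficients) == set(s["lasso"])


def test_planted_feature_recovery_beats_chance(rng):
    """Across seeded replicates the planted informative features reach the
    LASSO stage far more often than noise features would by chance."""
    hits = 0
    trials = 5
    for trial in range(trials):
        r = np.random.default_rng(trial)
        n = 100
        y = r.integers(0, 2, n)
        t = pd.DataFrame(r.normal(size=(n, 30)), columns=[f"f{i:02d}" for i in range(30)])
        t["f00"] += 1.8 * y
        report = run_cascade(t, y, seed=trial)
        hits += "f00" in report.coefficients
    assert hits >= 4  # chance rate would be far below
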