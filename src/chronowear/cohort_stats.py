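"""Cohort-level statistics: descriptives, correlations, tests, regressions,
and the cross-validated random-forest feature-importance model.

The headline cohort quantities are the social-jetlag tail fractions
(P(SJL > 1 h), P(SJL < 0)), the chronotype composition, and the breakdown
of the negative-SJL subset by chronotype.  Inference follows the
conventions of large-cohort sleep epidemiology: Pearson correlations with
pairwise deletion of missing values, two-sided two-sample t tests (Welch
by default), ordinary least squares for the SJL–nap/nocturnal-duration
relationship (SJL in hours against durations in minutes), and a random
forest regression whose tree-count × depth grid is selected by 5-fold
cross-validated R², reporting unit-sum impurity-based relative feature
importances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, KFold

from .sleep_records import axis_to_clock

logger = logging.getLogger("chronowear")

SIGNIFICANCE_LEVEL = 0.001

RF_FEATURES = ["sex_code", "age_years", "bmi", "steps_mean",
               "nocturnal_min", "mean_nap_min"]
RF_FEATURE_LABELS = {"sex_code": "sex", "age_years": "age", "bmi": "bmi",
                     "steps_mean": "exercise",
                     "nocturnal_min": "nocturnal_sleep",
                     "mean_nap_min": "daytime_nap"}
RF_TREES_GRID = (10, 20, 30, 40, 50)
RF_DEPTH_GRID = (2, 3, 4, 5)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float, int]:
    """Pearson product-moment correlation with pairwise deletion.

    Returns ``(r, two-sided p, n)``; requires n >= 3 complete pairs and
    non-degenerate variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("pearson requires at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson requires non-constant inputs")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    welch: bool


def two_sample_t(a, b, welch: bool = True) -> TTestResult:
    """Two-sided two-sample t test (Welch's by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t requires n >= 2 in both groups")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(t), p=float(p),
                       mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                       n_a=int(a.size),
                       mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                       n_b=int(b.size), welch=welch)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def sjl_regressions(summaries: pd.DataFrame) -> pd.DataFrame:
    """OLS fits of SJL (hours) on nap and nocturnal durations (minutes).

    Model 1: SJL ~ nap; model 2: SJL ~ nap + nocturnal sleep.  Returns a
    tidy table with one row per term.
    """
    data = summaries[["sjl_h", "mean_nap_min", "nocturnal_min"]].dropna()
    if data["mean_nap_min"].nunique() <= 1:
        raise ValueError("nap duration is constant: design is rank-deficient")
    rows = []
    specs = [("sjl~nap", ["mean_nap_min"]),
             ("sjl~nap+nocturnal", ["mean_nap_min", "nocturnal_min"])]
    for name, terms in specs:
        X = sm.add_constant(data[terms])
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"rank-deficient design in model {name}")
        fit = sm.OLS(data["sjl_h"], X).fit()
        for term in X.columns:
            rows.append({"model": name, "term": term,
                         "coef": float(fit.params[term]),
                         "stderr": float(fit.bse[term]),
                         "pvalue": float(fit.pvalues[term]),
                         "n": int(fit.nobs), "r2": float(fit.rsquared)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-forest feature importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    table: pd.DataFrame        # feature, importance (unit sum)
    n_estimators: int
    max_depth: int
    cv_r2: float
    n: int
    target: str
    method: str


def _rf_design(summaries: pd.DataFrame, subjects: pd.DataFrame | None,
               target: str) -> pd.DataFrame:
    df = summaries.copy()
    if subjects is not None:
        meta = subjects.set_index("subject_id")
        for col in ["age_years", "sex", "bmi"]:
            if col not in df.columns and col in meta.columns:
                df[col] = df["subject_id"].map(meta[col])
    df["sex_code"] = df["sex"].map({"male": 0.0, "female": 1.0})
    cols = RF_FEATURES + [target]
    return df[cols].dropna()  # complete cases only


def feature_importance(summaries: pd.DataFrame,
                       subjects: pd.DataFrame | None = None,
                       target: str = "sjl_h",
                       trees_grid=RF_TREES_GRID,
                       depth_grid=RF_DEPTH_GRID,
                       n_folds: int = 5,
                       seed: int = 0,
                       method: str = "impurity") -> ImportanceResult:
    """Grid-searched random-forest relative feature importance.

    Predictors are sex, age, BMI, mean daily steps (exercise), mean
    nocturnal sleep and mean daytime nap duration, on complete cases only;
    MSFsc is never a predictor.  The (tree count, depth) grid point with
    the best mean ``n_folds``-fold CV R² is refit on all complete cases;
    importances are normalised to unit sum.  ``method="permutation"``
    swaps in permutation importance on the refit model.
    """
    data = _rf_design(summaries, subjects, target)
    if len(data) < n_folds:
        raise ValueError("fewer complete cases than CV folds")
    X = data[RF_FEATURES].to_numpy()
    y = data[target].to_numpy()

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestRegressor(random_state=seed),
        param_grid={"n_estimators": list(trees_grid),
                    "max_depth": list(depth_grid)},
        scoring="r2", cv=cv)
    search.fit(X, y)
    best = search.best_estimator_

    if method == "permutation":
        perm = permutation_importance(best, X, y, n_repeats=10,
                                      random_state=seed)
        raw = np.clip(perm.importances_mean, 0.0, None)
    elif method == "impurity":
        raw = best.feature_importances_
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = raw.sum()
    importances = raw / total if total > 0 else raw

    table = pd.DataFrame({
        "feature": [RF_FEATURE_LABELS[f] for f in RF_FEATURES],
        "importance": importances})
    logger.info("feature importance (%s, n=%d): best trees=%d depth=%d "
                "cv R2=%.3f", target, len(data),
                search.best_params_["n_estimators"],
                search.best_params_["max_depth"], search.best_score_)
    return ImportanceResult(table=table,
                            n_estimators=int(search.best_params_["n_estimators"]),
                            max_depth=int(search.best_params_["max_depth"]),
                            cv_r2=float(search.best_score_),
                            n=int(len(data)), target=target, method=method)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Named cohort-level tables plus run metadata."""
    tables: dict = field(default_factory=dict)
    n: int = 0
    meta: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"n": self.n, "meta": self.meta, "tables": {}}
        for name, table in self.tables.items():
            fname = f"{name}.csv"
            table.to_csv(outdir / fname, index=False)
            manifest["tables"][name] = {"file": fname, "rows": int(len(table))}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _hist_table(values: pd.Series, bin_h: float = 0.5) -> pd.DataFrame:
    """Histogram with ``bin_h``-hour bins anchored at integer hours."""
    v = values.dropna().to_numpy()
    if v.size == 0:
        return pd.DataFrame(columns=["bin_left_h", "bin_right_h", "count"])
    lo = np.floor(v.min())
    hi = np.ceil(v.max()) + bin_h
    edges = np.arange(lo, hi + bin_h / 2, bin_h)
    counts, edges = np.histogram(v, bins=edges)
    return pd.DataFrame({"bin_left_h": edges[:-1], "bin_right_h": edges[1:],
                         "count": counts})


def _describe(group: pd.DataFrame, label: str) -> list[dict]:
    rows = []
    metrics = {"sjl_h": "sjl_h", "msfsc_h": "msfsc_h",
               "nocturnal_min": "nocturnal_sleep_min",
               "mean_nap_min": "nap_min",
               "total_24h_min": "total_sleep_min"}
    for col, metric in metrics.items():
        vals = group[col].dropna()
        if len(vals) == 0:
            continue
        rows.append({"group": label, "metric": metric,
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "n": int(len(vals))})
    return rows


def summarize_cohort(summaries: pd.DataFrame,
                     subjects: pd.DataFrame | None = None,
                     run_tests: bool = True) -> CohortReport:
    """Assemble the cohort-level report tables from per-subject summaries.

    Fractions use the subjects with a defined SJL (at least one work and
    one free night); chronotype shares use the chronotype cohort.
    Correlations/tests are computed on all subjects and on the zero- and
    long-nap subgroups (the short-nap subgroup is excluded from inference,
    its nap exposure being too weak), provided the inputs are
    non-degenerate.
    """
    df = summaries.copy()
    if subjects is not None:
        meta = subjects.set_index("subject_id")
        for col in ["age_years", "sex", "bmi"]:
            if col not in df.columns and col in meta.columns:
                df[col] = df["subject_id"].map(meta[col])
    if len(df) == 0:
        raise ValueError("empty cohort")
    df["total_24h_min"] = df["nocturnal_min"] + df["mean_nap_min"]

    report = CohortReport(n=len(df))
    sjl = df["sjl_h"].dropna()
    n_sjl = int(len(sjl))

    # --- headline fractions -------------------------------------------------
    frac_rows = []

    def frac(metric, num, den):
        frac_rows.append({"metric": metric, "numerator": int(num),
                          "denominator": int(den),
                          "value": float(num / den) if den else np.nan})

    frac("p_sjl_gt_1h", (sjl > 1.0).sum(), n_sjl)
    frac("p_sjl_lt_0", (sjl < 0.0).sum(), n_sjl)
    frac("p_napper", (df["mean_nap_min"] > 0).sum(), len(df))
    chrono = df["chronotype"].dropna()
    for ct in ["early", "intermediate", "late"]:
        frac(f"p_{ct}", (chrono == ct).sum(), len(chrono))
    report.tables["fractions"] = pd.DataFrame(frac_rows)

    # --- negative-SJL breakdown by chronotype -------------------------------
    ct_df = df.dropna(subset=["chronotype", "sjl_h"])
    neg = ct_df[ct_df["sjl_h"] < 0]
    rows = []
    for ct in ["early", "intermediate", "late"]:
        n_ct = int((ct_df["chronotype"] == ct).sum())
        n_neg_ct = int((neg["chronotype"] == ct).sum())
        rows.append({
            "chronotype": ct, "n": n_ct, "n_negative_sjl": n_neg_ct,
            "share_of_negative": n_neg_ct / len(neg) if len(neg) else np.nan,
            "share_within_chronotype": n_neg_ct / n_ct if n_ct else np.nan})
    report.tables["negative_sjl_by_chronotype"] = pd.DataFrame(rows)

    # --- descriptives -------------------------------------------------------
    desc = _describe(df, "all")
    if "sex" in df.columns:
        for sex in ["male", "female"]:
            desc += _describe(df[df["sex"] == sex], f"sex={sex}")
    for grp in ["zero", "short", "long"]:
        desc += _describe(df[df["nap_group"] == grp], f"nap={grp}")
    report.tables["descriptives"] = pd.DataFrame(desc)

    # --- schedule means (clock) by day type ---------------------------------
    sched_rows = []
    for day, onset_col, wake_col, dur_col in [
            ("work", "onset_work_axis", "wake_work_axis", "sdw"),
            ("free", "onset_free_axis", "wake_free_axis", "sdf")]:
        if onset_col not in df.columns:
            continue
        onset_ax = df[onset_col].dropna()
        wake_ax = df[wake_col].dropna()
        dur = df[dur_col].dropna()
        if len(onset_ax) == 0:
            continue
        sched_rows.append({
            "day_type": day,
            "onset_clock_h": float(axis_to_clock(onset_ax.mean())),
            "onset_sd_min": float(onset_ax.std(ddof=1) * 60) if len(onset_ax) > 1 else 0.0,
            "wake_clock_h": float(axis_to_clock(wake_ax.mean())),
            "wake_sd_min": float(wake_ax.std(ddof=1) * 60) if len(wake_ax) > 1 else 0.0,
            "duration_mean_min": float(dur.mean() * 60),
            "duration_sd_min": float(dur.std(ddof=1) * 60) if len(dur) > 1 else 0.0,
            "n": int(len(onset_ax))})
    report.tables["schedule_by_daytype"] = pd.DataFrame(sched_rows)

    # --- histograms ---------------------------------------------------------
    report.tables["hist_sjl"] = _hist_table(df["sjl_h"])
    report.tables["hist_msfsc"] = _hist_table(df["msfsc_h"])

    # --- correlations and tests ---------------------------------------------
    if run_tests:
        subsets = {"all": df,
                   "nap=zero": df[df["nap_group"] == "zero"],
                   "nap=long": df[df["nap_group"] == "long"]}
        corr_rows, test_rows = [], []
        pairs = [("sjl_h", "age_years"), ("sjl_h", "bmi"), ("sjl_h", "msfsc_h")]
        for label, sub in subsets.items():
            for xcol, ycol in pairs:
                if xcol not in sub.columns or ycol not in sub.columns:
                    continue
                try:
                    r, p, n = pearson(sub[xcol], sub[ycol])
                except ValueError:
                    continue
                corr_rows.append({"subset": label, "x": xcol, "y": ycol,
                                  "r": r, "p": p, "n": n})
            if "sex" in sub.columns:
                a = sub.loc[sub["sex"] == "male", "sjl_h"].dropna()
                b = sub.loc[sub["sex"] == "female", "sjl_h"].dropna()
                if len(a) >= 2 and len(b) >= 2:
                    res = two_sample_t(a, b, welch=True)
                    test_rows.append({
                        "subset": label, "test": "sjl_male_vs_female",
                        "t": res.t, "p": res.p,
                        "mean_male": res.mean_a, "sd_male": res.sd_a,
                        "n_male": res.n_a, "mean_female": res.mean_b,
                        "sd_female": res.sd_b, "n_female": res.n_b})
        report.tables["correlations"] = pd.DataFrame(corr_rows)
        report.tables["tests"] = pd.DataFrame(test_rows)
        try:
            report.tables["regressions"] = sjl_regressions(df)
        except ValueError as exc:
            logger.warning("SJL regressions skipped: %s", exc)

    report.meta = {"n_subjects": len(df), "n_sjl": n_sjl,
                   "n_chronotyped": int(len(chrono))}
    return report
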