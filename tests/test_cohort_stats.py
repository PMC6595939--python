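"""Cohort-level statistics against independent formula oracles."""

import numpy as np
import pandas as pd
import pytest

import chronowear as cw
from chronowear.synthetic_cohort import mu_age

RNG = np.random.default_rng(1234)

# fixed 10-point fixture for the correlation/t-test formula oracles
FIX_X = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 0.7, 6.3, 2.9, 3.8, 5.5])
FIX_Y = np.array([2.0, 3.1, 2.5, 6.0, 3.9, 1.1, 5.8, 3.5, 3.2, 5.0])


def oracle_pearson_r(x, y):
    """Product-moment r evaluated directly from the covariance formula."""
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def oracle_welch_t(a, b):
    """Welch statistic evaluated directly from its textbook formula."""
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


class TestPearson:
    def test_matches_covariance_formula(self):
        r, p, n = cw.pearson(FIX_X, FIX_Y)
        assert r == pytest.approx(oracle_pearson_r(FIX_X, FIX_Y), abs=1e-10)
        assert n == 10 and 0 < p < 1

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_perfect_linear_dependence(self, sign):
        r, p, _ = cw.pearson(FIX_X, sign * FIX_X)
        assert r == pytest.approx(sign, abs=1e-12)

    def test_pairwise_deletion(self):
        x = np.append(FIX_X, [np.nan, 2.0])
        y = np.append(FIX_Y, [1.0, np.nan])
        r, _, n = cw.pearson(x, y)
        assert n == 10
        assert r == pytest.approx(oracle_pearson_r(FIX_X, FIX_Y), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cw.pearson(np.ones(10), FIX_Y)
        with pytest.raises(ValueError):
            cw.pearson(FIX_X[:2], FIX_Y[:2])


class TestTwoSampleT:
    def test_matches_welch_formula(self):
        res = cw.two_sample_t(FIX_X, FIX_Y + 1.0, welch=True)
        assert res.t == pytest.approx(oracle_welch_t(FIX_X, FIX_Y + 1.0),
                                      abs=1e-10)

    def test_identical_samples(self):
        res = cw.two_sample_t(FIX_X, FIX_X)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        fwd = cw.two_sample_t(FIX_X, FIX_Y, welch=True)
        rev = cw.two_sample_t(FIX_Y, FIX_X, welch=True)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)

    def test_pooled_variance_variant(self):
        a, b = FIX_X, FIX_Y + 0.5
        res = cw.two_sample_t(a, b, welch=False)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) \
            / (a.size + b.size - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        assert res.t == pytest.approx(t, abs=1e-10)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            cw.two_sample_t(FIX_X, FIX_Y[:1])


class TestSjlRegressions:
    @staticmethod
    def _cohort(n=2000, slope=0.0066, noise=0.3, seed=7):
        rng = np.random.default_rng(seed)
        nap = rng.uniform(0, 120, n)
        noct = rng.normal(387, 50, n)
        sjl = slope * nap + rng.normal(0, noise, n)
        return pd.DataFrame({"sjl_h": sjl, "mean_nap_min": nap,
                             "nocturnal_min": noct})

    def test_recovers_generating_slope(self):
        table = cw.sjl_regressions(self._cohort())
        row = table[(table.model == "sjl~nap")
                    & (table.term == "mean_nap_min")].iloc[0]
        assert abs(row.coef - 0.0066) < 4 * row.stderr
        assert row.pvalue < 1e-3

    def test_noise_free_exact_recovery(self):
        data = self._cohort(noise=0.0)
        table = cw.sjl_regressions(data)
        row = table[(table.model == "sjl~nap")
                    & (table.term == "mean_nap_min")].iloc[0]
        assert row.coef == pytest.approx(0.0066, abs=1e-12)
        assert table[table.model == "sjl~nap"].iloc[0].r2 == pytest.approx(1.0)

    def test_constant_nap_is_rank_deficient(self):
        data = self._cohort(n=50)
        data["mean_nap_min"] = 30.0
        with pytest.raises(ValueError):
            cw.sjl_regressions(data)


class TestFeatureImportance:
    @staticmethod
    def _design(n=1500, seed=5, target_from_age=True):
        rng = np.random.default_rng(seed)
        age = rng.uniform(10, 80, n)
        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "age_years": age,
            "bmi": rng.normal(23, 3, n),
            "steps_mean": rng.normal(8000, 1500, n),
            "nocturnal_min": rng.normal(387, 50, n),
            "mean_nap_min": rng.uniform(0, 90, n),
        })
        df["msfsc_h"] = mu_age(age) if target_from_age \
            else rng.normal(3.6, 1.0, n)
        return df

    def test_age_driven_target_puts_age_first(self):
        res = cw.feature_importance(self._design(), target="msfsc_h", seed=0)
        table = res.table.set_index("feature")["importance"]
        assert table.idxmax() == "age"
        assert table["age"] > 0.95
        assert res.cv_r2 > 0.9

    def test_importances_sum_to_one(self):
        res = cw.feature_importance(self._design(n=400), target="msfsc_h",
                                    seed=3)
        assert res.table["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.table["importance"] >= 0).all()

    def test_pure_noise_has_no_cv_skill(self):
        res = cw.feature_importance(self._design(n=500, target_from_age=False),
                                    target="msfsc_h", seed=11)
        assert res.cv_r2 <= 0.0

    def test_seeded_runs_are_bit_reproducible(self):
        a = cw.feature_importance(self._design(n=400), target="msfsc_h", seed=9)
        b = cw.feature_importance(self._design(n=400), target="msfsc_h", seed=9)
        assert np.array_equal(a.table["importance"].to_numpy(),
                              b.table["importance"].to_numpy())
        assert (a.n_estimators, a.max_depth, a.cv_r2) \
            == (b.n_estimators, b.max_depth, b.cv_r2)

    def test_grid_point_comes_from_configured_grid(self):
        res = cw.feature_importance(self._design(n=400), target="msfsc_h",
                                    seed=2)
        assert res.n_estimators in cw.cohort_stats.RF_TREES_GRID
        assert res.max_depth in cw.cohort_stats.RF_DEPTH_GRID

    def test_too_few_complete_cases_rejected(self):
        with pytest.raises(ValueError):
            cw.feature_importance(self._design(n=4), target="msfsc_h")


def _toy_summaries(sjl_values, chronotypes=None, naps=None):
    n = len(sjl_values)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "sjl_h": sjl_values,
        "msfsc_h": [3.5] * n if chronotypes is None else
        [{"early": 2.0, "intermediate": 4.0, "late": 6.0}.get(c, np.nan)
         for c in chronotypes],
        "chronotype": ["intermediate"] * n if chronotypes is None
        else chronotypes,
        "mean_nap_min": [0.0] * n if naps is None else naps,
        "nap_group": ["zero"] * n if naps is None
        else [cw.classify_nap_group(v) for v in naps],
        "nocturnal_min": [387.0] * n,
    })


class TestSummarizeCohort:
    def test_counting_fractions(self):
        sjl = [-0.5, -0.2, -0.1, 0.1, 0.2, 0.3, 0.5, 1.2, 1.5, 0.8]
        rep = cw.summarize_cohort(_toy_summaries(sjl), run_tests=False)
        frac = rep.tables["fractions"].set_index("metric")["value"]
        assert frac["p_sjl_lt_0"] == pytest.approx(0.30)
        assert frac["p_sjl_gt_1h"] == pytest.approx(0.20)

    def test_identical_schedules_have_no_jetlag_tails(self):
        rep = cw.summarize_cohort(_toy_summaries([0.0] * 8), run_tests=False)
        frac = rep.tables["fractions"].set_index("metric")["value"]
        assert frac["p_sjl_lt_0"] == 0.0
        assert frac["p_sjl_gt_1h"] == 0.0

    def test_chronotype_proportions_sum_to_one(self, default_summaries,
                                               default_sim):
        rep = cw.summarize_cohort(default_summaries, default_sim.subjects)
        frac = rep.tables["fractions"].set_index("metric")["value"]
        total = frac["p_early"] + frac["p_intermediate"] + frac["p_late"]
        assert total == pytest.approx(1.0, abs=1e-12)
        assert ((rep.tables["fractions"]["value"].dropna() >= 0)
                & (rep.tables["fractions"]["value"].dropna() <= 1)).all()

    def test_negative_sjl_breakdown(self):
        chron = ["early"] * 4 + ["intermediate"] * 4 + ["late"] * 2
        sjl = [-0.3, -0.2, 0.1, 0.4, -0.1, 0.2, 0.3, 0.5, 0.6, 0.7]
        rep = cw.summarize_cohort(_toy_summaries(sjl, chronotypes=chron),
                                  run_tests=False)
        tab = rep.tables["negative_sjl_by_chronotype"].set_index("chronotype")
        assert tab.loc["early", "n_negative_sjl"] == 2
        assert tab.loc["early", "share_of_negative"] == pytest.approx(2 / 3)
        assert tab.loc["early", "share_within_chronotype"] == pytest.approx(0.5)
        assert tab["share_of_negative"].sum() == pytest.approx(1.0)

    def test_order_invariance(self):
        sjl = list(RNG.normal(0.3, 1.0, 40))
        base = _toy_summaries(sjl)
        shuffled = base.sample(frac=1.0, random_state=0).reset_index(drop=True)
        rep_a = cw.summarize_cohort(base, run_tests=False)
        rep_b = cw.summarize_cohort(shuffled, run_tests=False)
        pd.testing.assert_frame_equal(rep_a.tables["fractions"],
                                      rep_b.tables["fractions"])

    def test_add_then_remove_subject_is_identity(self):
        base = _toy_summaries(list(RNG.normal(0.3, 1.0, 30)))
        extra = pd.concat([base, _toy_summaries([5.0]).assign(
            subject_id="EXTRA")], ignore_index=True)
        back = extra[extra["subject_id"] != "EXTRA"].reset_index(drop=True)
        rep_a = cw.summarize_cohort(base, run_tests=False)
        rep_b = cw.summarize_cohort(back, run_tests=False)
        pd.testing.assert_frame_equal(rep_a.tables["fractions"],
                                      rep_b.tables["fractions"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cw.summarize_cohort(_toy_summaries([]))

    def test_histogram_bins_anchored_at_half_hours(self, default_summaries):
        rep = cw.summarize_cohort(default_summaries, run_tests=False)
        hist = rep.tables["hist_msfsc"]
        assert np.allclose((hist["bin_left_h"] * 2) % 1, 0.0)
        assert hist["count"].sum() \
            == default_summaries["msfsc_h"].notna().sum()

    def test_report_roundtrip(self, tmp_path):
        rep = cw.summarize_cohort(_toy_summaries([0.1, 0.2, -0.3, 0.9]),
                                  run_tests=False)
        rep.save(tmp_path)
        assert (tmp_path / "manifest.json").exists()
        frac = pd.read_csv(tmp_path / "fractions.csv")
        assert "p_sjl_lt_0" in frac["metric"].values
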