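"""Dichotomization, rank statistics, Kaplan–Meier/log-rank, Cox regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from vesselquant.cohort_statistics import (
    CoxConvergenceError,
    NotEstimableError,
    cox_fit,
    cox_partial_loglik,
    design_matrix,
    dichotomize,
    group_tests,
    km_logrank,
    spearman,
    subgroup_forest,
)
from vesselquant.synthetic_data import generate_cohort


class TestDichotomize:
    def test_simple_split(self):
        g = dichotomize([1, 2, 3, 4])
        assert g.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        g = dichotomize([5, 5, 5, 9])
        assert g.tolist() == ["low", "low", "low", "high"]

    def test_distinct_values_split_evenly(self, rng):
        vals = rng.normal(size=1000)
        g = dichotomize(vals)
        assert abs((g == "low").sum() - (g == "high").sum()) <= 1

    def test_missing_preserved(self):
        g = dichotomize([1.0, np.nan, 3.0])
        assert pd.isna(g.iloc[1])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(8.0)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_exact_p_matches_full_enumeration(self):
        x = np.array([1, 3, 2, 5, 4, 7, 6, 8.0])
        y = np.array([2, 1, 4, 3, 6, 5, 8, 7.0])
        rho, p = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            hits += abs(r) >= obs - 1e-12
            total += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestGroupTests:
    def test_separated_groups_tiny_p(self):
        vals = np.r_[np.arange(1, 11), np.arange(100, 111.0)]
        p = group_tests(vals, ["a"] * 10 + ["b"] * 11)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], ["a", "a"])

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            vals = rng.normal(size=40)
            groups = np.array(["a"] * 20 + ["b"] * 20)
            rejections += group_tests(vals, groups) < 0.05
        assert 0.02 <= rejections / n_sims <= 0.08

    def test_three_group_null_p_uniform(self, rng):
        ps = [
            group_tests(rng.normal(size=45), np.repeat(["a", "b", "c"], 15))
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestKmLogrank:
    def test_no_censoring_matches_empirical_survival(self):
        time = [1, 2, 3, 4, 5.0]
        res = km_logrank(time, [1] * 5, ["g"] * 5)
        curves = res["curves"].set_index("time")["survival"]
        for i, t in enumerate(time, start=1):
            assert curves.loc[t] == pytest.approx(1 - i / 5)

    def test_identical_groups_chi2_zero(self):
        time = [2, 4, 6, 2, 4, 6.0]
        event = [1, 1, 0, 1, 1, 0]
        res = km_logrank(time, event, ["a"] * 3 + ["b"] * 3)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_six_subject_fixture_matches_hand_calculation(self):
        # groups A={1,3,5 all events}, B={2,4,6 all events}; O_A=3.
        # E_A at times 1..6: 3/6, 2/5, 2/4, 1/3, 1/2, 0/1 -> E_A=2.533333
        # V at each time d*(n_A/n)*(1-n_A/n) (d=1, no ties)
        time = [1, 2, 3, 4, 5, 6.0]
        event = [1] * 6
        group = ["A", "B", "A", "B", "A", "B"]
        na = np.array([3, 2, 2, 1, 1, 0])
        n = np.array([6, 5, 4, 3, 2, 1])
        e_a = float((na / n).sum())
        v = float(((na / n) * (1 - na / n)).sum())
        expected_chi2 = (3 - e_a) ** 2 / v
        res = km_logrank(time, event, group)
        assert res["chi2"] == pytest.approx(expected_chi2, rel=1e-9)

    def test_no_events_flagged(self):
        with pytest.raises(NotEstimableError):
            km_logrank([1, 2, 3.0], [0, 0, 0], ["a", "a", "b"])


class TestCoxFit:
    def test_identical_groups_hr_one(self):
        # both groups share the exact same time/event vectors, so the
        # partial likelihood is symmetric in the group label and the MLE
        # sits at coefficient 0
        time = [1, 2, 3, 4.0] * 2
        event = [1, 1, 0, 1] * 2
        x = pd.DataFrame({"g": [0.0] * 4 + [1.0] * 4})
        res = cox_fit(time, event, x)
        assert res.table["hr"][0] == pytest.approx(1.0, abs=1e-6)
        assert res.table["p"][0] == pytest.approx(1.0, abs=1e-6)

    def test_eight_subject_fixture_matches_brute_force_likelihood(self):
        time = np.array([2.0, 5.0, 3.0, 8.0, 1.0, 9.0, 4.0, 7.0])
        event = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0])

        def neg_pl(b):
            return -cox_partial_loglik(np.array([b]), time, event, x.reshape(-1, 1))

        brute = minimize_scalar(
            neg_pl, bounds=(-5, 5), method="bounded", options={"xatol": 1e-12}
        )
        res = cox_fit(pd.Series(time), pd.Series(event), pd.DataFrame({"x": x}))
        assert res.table["coef"][0] == pytest.approx(brute.x, abs=1e-6)

    def test_matches_reference_implementations(self):
        import statsmodels.api as sm  # noqa: F401
        from statsmodels.duration.hazard_regression import PHReg

        df = generate_cohort(300, np.log(2.0), seed=4)
        x = (dichotomize(df["size_um"]) == "high").astype(float).to_frame("high")
        for ties in ("breslow", "efron"):
            ours = cox_fit(df["time"], df["event"], x, ties=ties)
            ref = PHReg(df["time"], x, status=df["event"], ties=ties).fit()
            assert ours.table["coef"][0] == pytest.approx(ref.params[0], abs=1e-5)
            assert ours.table["se"][0] == pytest.approx(
                float(np.sqrt(ref.cov_params()[0, 0])), abs=1e-5
            )

    def test_doubled_dataset_same_coef_smaller_se(self):
        df = generate_cohort(200, np.log(2.0), seed=9)
        x = (dichotomize(df["size_um"]) == "high").astype(float).to_frame("high")
        single = cox_fit(df["time"], df["event"], x)
        df2 = pd.concat([df, df], ignore_index=True)
        x2 = pd.concat([x, x], ignore_index=True)
        double = cox_fit(df2["time"], df2["event"], x2)
        assert double.table["coef"][0] == pytest.approx(
            single.table["coef"][0], abs=1e-6
        )
        assert double.table["se"][0] == pytest.approx(
            single.table["se"][0] / np.sqrt(2), rel=0.01
        )

    def test_ci_brackets_hr(self):
        df = generate_cohort(200, np.log(3.0), seed=3)
        x = (dichotomize(df["size_um"]) == "high").astype(float).to_frame("high")
        t = cox_fit(df["time"], df["event"], x).table.iloc[0]
        assert t["ci_low"] < t["hr"] < t["ci_high"]
        assert t["hr"] > 0

    def test_separation_raises_diagnostic(self):
        # events only in one covariate group, perfectly ordered: monotone
        time = pd.Series([1, 2, 3, 4, 10, 11, 12, 13.0])
        event = pd.Series([1, 1, 1, 1, 1, 1, 1, 1])
        x = pd.DataFrame({"g": [1, 1, 1, 1, 0, 0, 0, 0.0]})
        with pytest.raises(CoxConvergenceError):
            cox_fit(time, event, x)

    def test_no_events_not_estimable(self):
        with pytest.raises(NotEstimableError):
            cox_fit([1, 2.0], [0, 0], pd.DataFrame({"x": [0, 1.0]}))


class TestDesignMatrixAndForest:
    def test_reference_level_coding(self):
        df = pd.DataFrame({"grade": ["1", "2", "3", "1"], "age": [50, 61, 70, 45.0]})
        x, refs = design_matrix(df, {"grade": "1", "age": None})
        assert refs == {"grade": "1"}
        assert list(x.columns) == ["grade[2]", "grade[3]", "age"]
        assert x["grade[2]"].tolist() == [0, 1, 0, 0]

    def test_whole_cohort_subgroup_equals_univariable_fit(self):
        df = generate_cohort(200, np.log(2.5), seed=6)
        df["size_group"] = dichotomize(df["size_um"])
        forest = subgroup_forest(df, "size_group")
        x = (df["size_group"] == "high").astype(float).to_frame("high")
        uni = cox_fit(df["time"], df["event"], x)
        row = forest.iloc[0]
        assert row["estimable"]
        assert row["hr"] == pytest.approx(uni.table["hr"][0], rel=1e-9)

    def test_zero_event_subgroup_flagged_not_fitted(self):
        df = generate_cohort(100, 0.0, seed=2)
        df["size_group"] = dichotomize(df["size_um"])
        df.loc[df.index[:50], "event"] = 0
        forest = subgroup_forest(
            df,
            "size_group",
            subgroups={"dead_zone": pd.Series(df.index < 50, index=df.index)},
        )
        assert not forest.iloc[0]["estimable"]

    def test_effect_only_in_one_stratum_recovered(self):
        hrs_a, hrs_b = [], []
        for seed in range(10):
            a = generate_cohort(250, np.log(3.0), seed=seed)
            b = generate_cohort(250, 0.0, seed=seed + 1000)
            a["stratum"], b["stratum"] = "A", "B"
            df = pd.concat([a, b], ignore_index=True)
            df["size_group"] = dichotomize(df["size_um"])
            forest = subgroup_forest(
                df,
                "size_group",
                subgroups={
                    "A": df["stratum"] == "A",
                    "B": df["stratum"] == "B",
                },
            )
            hrs_a.append(forest.set_index("subgroup").loc["A", "hr"])
            hrs_b.append(forest.set_index("subgroup").loc["B", "hr"])
        assert abs(np.mean(hrs_a) - 3.0) / 3.0 < 0.25
        assert abs(np.mean(hrs_b) - 1.0) < 0.2
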