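"""Tests for the statistical decision tree and candidate filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nmjkit.stats import (
    assess_normality,
    assess_variance_homogeneity,
    categorical_test,
    dunn_test,
    filter_pulldown_candidates,
    se_kurtosis,
    se_skewness,
    select_and_run,
)


def make_table(**groups):
    return pd.concat(
        [pd.DataFrame({"group": k, "value": v}) for k, v in groups.items()],
        ignore_index=True,
    )


class TestNormality:
    def test_two_point_sample_flagged_non_normal(self):
        # {-1,+1} x50: skewness 0, excess kurtosis -2; |−2| far exceeds
        # 1.96 * SE_kurt(100) ~ 0.94
        table = make_table(a=np.repeat([-1.0, 1.0], 50))
        table = pd.concat([table, make_table(b=np.random.default_rng(0).normal(size=100))],
                          ignore_index=True)
        res = assess_normality(table)
        row = res.per_group.set_index("group").loc["a"]
        assert row["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert row["kurtosis"] == pytest.approx(-2.0, abs=0.15)
        assert not row["normal"]
        assert not res.normal

    def test_se_formulas(self):
        # closed forms at n=100
        assert se_skewness(100) == pytest.approx(
            np.sqrt(6 * 100 * 99 / (98 * 101 * 103))
        )
        assert se_kurtosis(100) == pytest.approx(
            2 * se_skewness(100) * np.sqrt((100**2 - 1) / (97 * 105))
        )

    def test_gaussian_samples_usually_pass(self):
        # each of the four moment screens (2 groups x 2 moments) is
        # calibrated near 5%, so the joint pass rate sits near 0.95^4
        hits = 0
        per_group_hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            table = make_table(a=rng.normal(size=200), b=rng.normal(size=200))
            res = assess_normality(table)
            hits += res.normal
            per_group_hits += res.per_group["normal"].sum()
        assert per_group_hits / 400 == pytest.approx(0.95**2, abs=0.04)
        assert hits / 200 > 0.70

    def test_exponential_samples_fail(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table = make_table(a=rng.exponential(size=200))
            table = pd.concat(
                [table, make_table(b=rng.exponential(size=200))],
                ignore_index=True,
            )
            hits += not assess_normality(table).normal
        assert hits >= 99

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            assess_normality(make_table(a=[1.0, 2.0, 3.0], b=np.arange(10.0)))


class TestLevene:
    def test_unequal_variances_detected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table = make_table(a=rng.normal(0, 1, 100), b=rng.normal(0, 5, 100))
            homogeneous, _, p = assess_variance_homogeneity(table)
            hits += not homogeneous
        assert hits >= 49

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_reps = 1000
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            table = make_table(a=rng.normal(size=50), b=rng.normal(size=50))
            homogeneous, _, _ = assess_variance_homogeneity(table)
            rejections += not homogeneous
        assert rejections / n_reps == pytest.approx(0.05, abs=0.02)

    def test_constant_groups_flagged_homogeneous(self):
        table = make_table(a=np.full(10, 2.0), b=np.full(10, 5.0))
        with pytest.warns(UserWarning):
            homogeneous, _, _ = assess_variance_homogeneity(table)
        assert homogeneous


class TestRouting:
    def test_two_normal_groups_student_t(self):
        rng = np.random.default_rng(1)
        table = make_table(a=rng.normal(10, 2, 40), b=rng.normal(11, 2, 40))
        res = select_and_run(table)
        assert res.test_name == "student_t"
        t, p = sps.ttest_ind(
            table.loc[table.group == "a", "value"],
            table.loc[table.group == "b", "value"],
        )
        assert res.p_value == pytest.approx(p)

    def test_unequal_variance_routes_to_welch(self):
        rng = np.random.default_rng(2)
        table = make_table(
            a=rng.normal(10, 1, 60), b=rng.normal(10, 5, 60), c=rng.normal(10, 1, 60)
        )
        res = select_and_run(table)
        assert res.test_name == "welch_anova"
        assert res.posthoc_method == "games_howell"
        # independent oracle: Welch's F computed from the textbook formula
        groups = [g["value"].to_numpy() for _, g in table.groupby("group")]
        w = [len(g) / g.var(ddof=1) for g in groups]
        ybar = sum(wi * g.mean() for wi, g in zip(w, groups)) / sum(w)
        k = len(groups)
        num = sum(wi * (g.mean() - ybar) ** 2 for wi, g in zip(w, groups)) / (k - 1)
        lam = sum(
            (1 - wi / sum(w)) ** 2 / (len(g) - 1) for wi, g in zip(w, groups)
        )
        f_welch = num / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
        assert res.statistic == pytest.approx(f_welch, rel=1e-6)

    def test_exponential_groups_route_nonparametric(self):
        rng = np.random.default_rng(3)
        table = make_table(
            a=rng.exponential(1, 60), b=rng.exponential(1, 60),
            c=rng.exponential(1, 60),
        )
        res = select_and_run(table)
        assert res.test_name == "kruskal_wallis"
        assert res.posthoc_method == "dunn"
        assert len(res.posthoc) == 3

    def test_two_skewed_groups_mann_whitney(self):
        rng = np.random.default_rng(4)
        table = make_table(a=rng.exponential(1, 60), b=rng.exponential(2, 60))
        res = select_and_run(table)
        assert res.test_name == "mann_whitney_u"

    def test_anova_with_dunnett_control(self):
        rng = np.random.default_rng(5)
        table = make_table(
            ctrl=rng.normal(10, 2, 40), m1=rng.normal(8, 2, 40),
            m2=rng.normal(10, 2, 40),
        )
        res = select_and_run(table, control_label="ctrl")
        assert res.test_name == "one_way_anova"
        assert res.posthoc_method == "dunnett"
        assert set(res.posthoc["group2"]) == {"ctrl"}
        assert len(res.posthoc) == 2

    def test_anova_bonferroni_without_control(self):
        rng = np.random.default_rng(6)
        table = make_table(
            a=rng.normal(10, 2, 40), b=rng.normal(8, 2, 40),
            c=rng.normal(10, 2, 40),
        )
        res = select_and_run(table)
        assert res.posthoc_method == "bonferroni"
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15).all()

    def test_routing_deterministic(self):
        rng = np.random.default_rng(7)
        table = make_table(a=rng.normal(10, 2, 30), b=rng.normal(9, 2, 30))
        r1, r2 = select_and_run(table), select_and_run(table)
        assert r1.test_name == r2.test_name and r1.p_value == r2.p_value

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            select_and_run(make_table(a=np.arange(10.0)))


class TestDunn:
    def test_matches_asymptotic_mann_whitney_for_two_groups(self):
        # independent identity: Dunn's z for one pair (no adjustment)
        # equals the tie-corrected normal approximation of Mann-Whitney U
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = np.round(rng.exponential(1.0, 12), 2)
            b = np.round(rng.exponential(2.0, 10), 2)
            ours = dunn_test({"a": a, "b": b}, adjust="none")
            _, p_mw = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            assert ours["p_raw"].iloc[0] == pytest.approx(p_mw, rel=1e-12)

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.exponential(1, 20) for g in "abc"}
        res = dunn_test(groups)
        assert np.allclose(
            res["p_adj"], np.minimum(1.0, 3 * res["p_raw"])
        )


class TestCategorical:
    def test_perfect_independence(self):
        res = categorical_test(np.array([[50, 50], [50, 50]]))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # [[90,10],[10,90]]: every expected cell is 50, sum (O-E)^2/E = 128
        res = categorical_test(np.array([[90, 10], [10, 90]]))
        assert res.chi2 == pytest.approx(128.0)

    def test_three_group_pairwise_bonferroni(self):
        counts = pd.DataFrame(
            {"g1": [30, 70], "g2": [50, 50], "g3": [70, 30]}, index=["yes", "no"]
        )
        res = categorical_test(counts)
        assert len(res.pairwise) == 3
        assert np.allclose(
            res.pairwise["p_adj"], np.minimum(1.0, 3 * res.pairwise["p_raw"])
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            categorical_test(np.array([[0, 0], [5, 5]]))


class TestPulldownFilter:
    SAMPLE = pd.DataFrame({"protein": ["A", "B", "C"], "peptides": [3, 2, 1]})
    CONTROL = pd.DataFrame({"protein": ["B"], "peptides": [1]})

    def test_both_rules_applied(self):
        # C fails the >=2-peptide rule, B is present in the mock control
        assert filter_pulldown_candidates(self.SAMPLE, self.CONTROL) == ["A"]

    def test_single_peptide_excluded(self):
        sample = pd.DataFrame({"protein": ["X"], "peptides": [1]})
        empty = pd.DataFrame({"protein": [], "peptides": []})
        assert filter_pulldown_candidates(sample, empty) == []

    def test_control_presence_excludes_regardless_of_count(self):
        sample = pd.DataFrame({"protein": ["Y"], "peptides": [10]})
        control = pd.DataFrame({"protein": ["Y"]})
        assert filter_pulldown_candidates(sample, control) == []

    def test_order_preserved(self):
        sample = pd.DataFrame(
            {"protein": ["Z", "A", "M"], "peptides": [5, 5, 5]}
        )
        empty = pd.DataFrame({"protein": []})
        assert filter_pulldown_candidates(sample, empty) == ["Z", "A", "M"]
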