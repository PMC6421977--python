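"""Statistics cards: descriptives, gates, decision tree, frozen oracles.

The hard-coded expected statistics and p-values in ``R_ORACLE`` were computed
independently in R (t.test, ks.test, wilcox.test, aov, kruskal.test,
car::leveneTest, cor.test, nortest::lillie.test) on the small samples below
and frozen here.
"""

import itertools

import numpy as np
import pytest

from cardlink.stats import (
    StatsConfig,
    column_statistics,
    correlation_card,
    ks_normality,
    means_comparison_card,
    select_means_test,
)

G1 = [3.1, 4.5, 2.2, 5.0, 3.3, 4.1, 2.9, 3.7]
G2 = [5.2, 6.1, 4.8, 5.9, 6.4, 5.5, 4.9, 6.0]
G3 = [4.0, 3.5, 5.1, 4.4, 4.9, 3.8, 4.6, 4.2]

R_ORACLE = {
    "student_t": (-5.20755643923, 0.000132739308117),
    "student_greater_p": 0.999933630346,
    "student_less_p": 6.63696540586e-05,
    "welch_p": 0.000219634388581,
    "ks2_two": (0.875, 0.0024864024864),
    "ks2_less_p": 0.0012432012432,   # mu1 < mu2 one-sided
    "mannwhitney": (2.0, 0.000621600621601),
    "anova": (16.6811209083, 4.59917923566e-05),
    "kruskal": (14.2424423662, 0.000807779701624),
    "levene": (1.27990970655, 0.276923531708),
    "pearson": (0.993053239697, 1.01037447797e-08),
    "spearman_rho": 1.0,
    "lilliefors_stat": 0.0892405696247,
}


class TestColumnStatistics:
    def test_closed_form(self):
        cs = column_statistics([2, 4, 6])
        assert (cs.mean, cs.sd, cs.n, cs.min, cs.max) == (4, 2, 3, 2, 6)

    def test_single_value_degenerate(self):
        with pytest.warns(UserWarning, match="n=1"):
            cs = column_statistics([5])
        assert (cs.mean, cs.sd, cs.n) == (5, 0, 1)

    def test_missing_excluded(self):
        assert column_statistics([2, None, 6]).n == 2

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            column_statistics([None, None])


class TestNormalityGate:
    def test_large_normal_sample_passes(self):
        rng = np.random.default_rng(8)
        res = ks_normality(rng.normal(size=5000))
        assert res.is_normal and res.test_name == "lilliefors_ks"

    def test_large_uniform_sample_fails(self):
        rng = np.random.default_rng(8)
        res = ks_normality(rng.random(5000))
        assert not res.is_normal

    def test_constant_sample_non_normal_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = ks_normality([3.0] * 10)
        assert not res.is_normal and res.p_value == 0.0

    def test_statistic_matches_r_nortest(self):
        z = [2.3, 3.1, 1.8, 2.9, 3.4, 2.1, 2.7, 3.0, 2.5, 2.8, 1.9, 3.3, 2.2, 2.6, 3.2]
        res = ks_normality(z)
        assert res.statistic == pytest.approx(R_ORACLE["lilliefors_stat"], rel=1e-8)
        assert res.is_normal

    def test_naive_variant_available(self):
        rng = np.random.default_rng(8)
        res = ks_normality(rng.normal(size=200), StatsConfig(lilliefors=False))
        assert res.test_name == "ks_naive"

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ks_normality([1.0, 2.0])


class TestCorrelationCard:
    def test_linear_normal_both_coefficients_near_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=500)
        y = 2 * x + rng.normal(scale=0.1, size=500)
        rep = correlation_card(x, y)
        assert rep.pearson is not None
        assert rep.pearson["r"] > 0.97 and rep.spearman["rho"] > 0.97

    def test_monotone_cubic_spearman_exactly_one(self):
        x = [1.2, 2.4, 3.1, 4.8, 5.5, 6.1, 7.9, 8.2, 9.6, 10.1]
        rep = correlation_card(x, [v**3 for v in x])
        assert rep.spearman["rho"] == pytest.approx(1.0)

    def test_non_normal_x_drops_pearson(self):
        rng = np.random.default_rng(10)
        x = rng.exponential(size=800)
        y = x + rng.normal(scale=0.2, size=800)
        rep = correlation_card(x, y)
        assert rep.pearson is None and rep.spearman is not None
        assert any("only Spearman" in line for line in rep.narrative)

    def test_gate_invariant_on_simulated_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            n = int(rng.integers(20, 120))
            x = rng.exponential(size=n) if rng.random() < 0.5 else rng.normal(size=n)
            y = x + rng.normal(scale=0.5, size=n)
            rep = correlation_card(x, y)
            both_normal = rep.normality_x.is_normal and rep.normality_y.is_normal
            assert (rep.pearson is not None) == both_normal

    def test_pairwise_complete_and_frozen_r_values(self):
        x = [1.2, 2.4, 3.1, 4.8, 5.5, 6.1, 7.9, 8.2, 9.6, 10.1]
        y = [2.0, 2.9, 4.2, 5.1, 6.6, 6.9, 8.8, 9.9, 10.5, 12.0]
        rep = correlation_card(x, y)
        assert rep.n == 10
        assert rep.pearson["r"] == pytest.approx(R_ORACLE["pearson"][0], rel=1e-8)
        assert rep.pearson["p"] == pytest.approx(R_ORACLE["pearson"][1], rel=1e-6)
        assert rep.spearman["rho"] == pytest.approx(R_ORACLE["spearman_rho"])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlation_card([1, 1, 1, 1], [1, 2, 3, 4])


class TestSelectMeansTest:
    def test_full_truth_table(self):
        """Exhaustive enumeration of every branch of the decision tree."""
        expected = {
            (2, True, True): "student_t",
            (2, True, False): "welch_t",
            (2, False, True): "ks_two_sample",
            (2, False, False): "ks_two_sample",
            (3, True, True): "one_way_anova",
            (3, True, False): "kruskal_wallis",
            (3, False, True): "kruskal_wallis",
            (3, False, False): "kruskal_wallis",
        }
        for (k, normal, homo), want in expected.items():
            assert select_means_test(k, normal, homo) == want
        for normal, homo in itertools.product([True, False], repeat=2):
            assert select_means_test(5, normal, homo) == expected[(3, normal, homo)]

    def test_mannwhitney_option(self):
        assert select_means_test(2, False, True, nonparametric="mannwhitney") == "mann_whitney_u"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            select_means_test(1, True, True)


class TestMeansComparisonCard:
    def test_identical_groups_t_is_zero_p_is_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        rep = means_comparison_card(None, groups={"a": g, "b": list(g)})
        assert rep.results["two_sided"]["statistic"] == 0.0
        assert rep.results["two_sided"]["p"] == 1.0

    def test_frozen_r_student_and_levene(self):
        rep = means_comparison_card(None, groups={"a": G1, "b": G2})
        assert rep.chosen_test == "student_t"
        stat, p = R_ORACLE["student_t"]
        assert rep.results["two_sided"]["statistic"] == pytest.approx(stat, rel=1e-8)
        assert rep.results["two_sided"]["p"] == pytest.approx(p, rel=1e-6)
        assert rep.results["greater"]["p"] == pytest.approx(R_ORACLE["student_greater_p"], rel=1e-6)
        assert rep.results["less"]["p"] == pytest.approx(R_ORACLE["student_less_p"], rel=1e-6)
        assert rep.homoscedasticity["statistic"] == pytest.approx(R_ORACLE["levene"][0], rel=1e-8)
        assert rep.homoscedasticity["p"] == pytest.approx(R_ORACLE["levene"][1], rel=1e-6)

    def test_forced_nonnormal_branch_matches_r_ks(self):
        cfg = StatsConfig(alpha=0.9999)  # every gate fails: nonparametric branch
        rep = means_comparison_card(None, groups={"a": G1, "b": G2}, config=cfg)
        assert rep.chosen_test == "ks_two_sample"
        stat, p = R_ORACLE["ks2_two"]
        assert rep.results["two_sided"]["statistic"] == pytest.approx(stat)
        assert rep.results["two_sided"]["p"] == pytest.approx(p, rel=1e-6)
        # G1 sits below G2, so the mu1<mu2 tab carries the small p
        assert rep.results["less"]["p"] == pytest.approx(R_ORACLE["ks2_less_p"], rel=1e-6)
        assert rep.results["greater"]["p"] == pytest.approx(1.0)

    def test_mannwhitney_matches_r_wilcox(self):
        cfg = StatsConfig(alpha=0.9999, nonparametric="mannwhitney")
        rep = means_comparison_card(None, groups={"a": G1, "b": G2}, config=cfg)
        assert rep.chosen_test == "mann_whitney_u"
        stat, p = R_ORACLE["mannwhitney"]
        assert rep.results["two_sided"]["statistic"] == pytest.approx(stat)
        assert rep.results["two_sided"]["p"] == pytest.approx(p, rel=1e-6)

    def test_three_groups_anova_matches_r(self):
        rep = means_comparison_card(None, groups={"a": G1, "b": G2, "c": G3})
        assert rep.chosen_test == "one_way_anova"
        stat, p = R_ORACLE["anova"]
        assert rep.results["two_sided"]["statistic"] == pytest.approx(stat, rel=1e-8)
        assert rep.results["two_sided"]["p"] == pytest.approx(p, rel=1e-6)
        assert "not_applicable" in rep.results["greater"]

    def test_nonnormal_many_groups_kruskal_matches_r(self):
        cfg = StatsConfig(alpha=0.9999)
        rep = means_comparison_card(None, groups={"a": G1, "b": G2, "c": G3, "d": [1.0, 9.0, 2.0, 8.0]},
                                    config=cfg)
        assert rep.chosen_test == "kruskal_wallis"
        rep3 = means_comparison_card(None, groups={"a": G1, "b": G2, "c": G3}, config=cfg)
        stat, p = R_ORACLE["kruskal"]
        assert rep3.results["two_sided"]["statistic"] == pytest.approx(stat, rel=1e-8)
        assert rep3.results["two_sided"]["p"] == pytest.approx(p, rel=1e-6)

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            rep = means_comparison_card(None, groups={"a": G1, "b": G2, "tiny": [1.0]})
        assert rep.excluded_groups == ["tiny"]
        assert len(rep.groups) == 2

    def test_fewer_than_two_usable_groups_rejected(self):
        with pytest.raises(ValueError, match="2 usable groups"):
            means_comparison_card(None, groups={"a": G1, "tiny": [1.0]})

    def test_on_dataset_with_filter(self, ad_dataset):
        from cardlink.coordination import Board, CheckedSet
        from conftest import NEUN

        board = Board(ad_dataset)
        card = board.create_filter("Region")
        board.set_predicate(card, CheckedSet({"CA1", "DG"}))
        rep = means_comparison_card(ad_dataset, NEUN, "Condition", board.filter_state)
        n_expected = {
            cond: sum(
                1 for r in ad_dataset.rows
                if r.row_id in board.active_rows and r.values["Condition"] == cond
                and r.values.get(NEUN) is not None
            )
            for cond in ("AD", "Control")
        }
        got = {g["value"]: g["stats"].n for g in rep.groups}
        assert got == n_expected
        assert any("Decision" in line for line in rep.narrative)

    def test_narrative_mentions_every_gate(self):
        rep = means_comparison_card(None, groups={"a": G1, "b": G2})
        text = " ".join(rep.narrative)
        assert "normality" in text and "Homoscedasticity" in text and "Decision" in text
        assert "no multiple-testing correction" in text.lower()
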