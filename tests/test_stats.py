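"""Factorial ANOVA, SNK post-hoc, transforms, derived arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ratvar import (EmptyCellError, SummaryCell, anova_from_summary,
                    fold_change, log_transform_outcome,
                    normalize_densitometry, percent_difference,
                    pooled_summary, snk_posthoc, two_way_anova)


def _random_design(rng, ns=(9, 7, 9, 5), mus=(10, 12, 8, 15), sd=3.0):
    rows = []
    cells = [(False, False), (False, True), (True, False), (True, True)]
    for (diab, den), n, mu in zip(cells, ns, mus):
        for v in rng.normal(mu, sd, n):
            rows.append({"diabetes": diab, "denervation": den, "y": v})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_cells_give_f_zero_p_one(self):
        rows = []
        for diab in (False, True):
            for den in (False, True):
                for v in (1.0, 2.0, 3.0):
                    rows.append({"diabetes": diab, "denervation": den,
                                 "y": v})
        table = two_way_anova(pd.DataFrame(rows), "y")
        for effect in ("denervation", "diabetes", "interaction"):
            assert table.effect(effect).f == pytest.approx(0.0, abs=1e-20)
            assert table.p(effect) == pytest.approx(1.0)

    def test_balanced_design_matches_cell_means_decomposition(self):
        # oracle: classical balanced two-way formulas from cell means
        rng = np.random.default_rng(0)
        n = 6
        df = _random_design(rng, ns=(n, n, n, n))
        table = two_way_anova(df, "y")
        cm = df.groupby(["diabetes", "denervation"])["y"].mean()
        grand = cm.mean()
        a_means = cm.groupby("denervation").mean()  # denervation margins
        b_means = cm.groupby("diabetes").mean()
        ss_a = 2 * n * ((a_means - grand) ** 2).sum()
        ss_b = 2 * n * ((b_means - grand) ** 2).sum()
        ss_ab = n * sum(
            (cm[(d, e)] - a_means[e] - b_means[d] + grand) ** 2
            for d in (False, True) for e in (False, True))
        assert table.effect("denervation").ss == pytest.approx(ss_a)
        assert table.effect("diabetes").ss == pytest.approx(ss_b)
        assert table.effect("interaction").ss == pytest.approx(ss_ab)

    def test_unbalanced_type3_matches_statsmodels(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        rng = np.random.default_rng(1)
        df = _random_design(rng)
        table = two_way_anova(df, "y")
        fit = smf.ols("y ~ C(denervation, Sum)*C(diabetes, Sum)", df).fit()
        sm_tab = anova_lm(fit, typ=3)
        assert table.p("denervation") == pytest.approx(
            sm_tab.loc["C(denervation, Sum)", "PR(>F)"], abs=1e-12)
        assert table.p("diabetes") == pytest.approx(
            sm_tab.loc["C(diabetes, Sum)", "PR(>F)"], abs=1e-12)
        assert table.p("interaction") == pytest.approx(
            sm_tab.loc["C(denervation, Sum):C(diabetes, Sum)", "PR(>F)"],
            abs=1e-12)

    def test_cell_with_too_few_observations_rejected(self):
        rng = np.random.default_rng(2)
        df = _random_design(rng, ns=(5, 5, 5, 1))
        with pytest.raises(EmptyCellError):
            two_way_anova(df, "y")


class TestAnovaFromSummary:
    def test_equivalent_to_raw_anova_on_random_data(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            ns = rng.integers(3, 12, 4)
            df = _random_design(rng, ns=ns,
                                mus=rng.normal(10, 4, 4),
                                sd=float(rng.uniform(0.5, 4)))
            raw = two_way_anova(df, "y")
            cells = {}
            for (diab, den), sub in df.groupby(["diabetes", "denervation"]):
                cells[(diab, den)] = SummaryCell(
                    mean=float(sub["y"].mean()),
                    sd=float(sub["y"].std(ddof=1)), n=len(sub))
            summary = anova_from_summary(cells)
            for effect in ("denervation", "diabetes", "interaction"):
                assert summary.p(effect) == pytest.approx(raw.p(effect),
                                                          abs=1e-9)

    def test_equal_cells_give_zero_f(self):
        cell = SummaryCell(mean=10.0, sd=2.0, n=6)
        cells = {k: cell for k in [(False, False), (False, True),
                                   (True, False), (True, True)]}
        table = anova_from_summary(cells)
        for effect in ("denervation", "diabetes", "interaction"):
            assert table.effect(effect).f == pytest.approx(0.0, abs=1e-18)

    def test_initial_weight_row_reproduces_printed_interaction_p(self):
        cells = {(False, False): SummaryCell(258, 14, 9),
                 (False, True): SummaryCell(267, 29, 7),
                 (True, False): SummaryCell(269, 13, 9),
                 (True, True): SummaryCell(272, 28, 5)}
        table = anova_from_summary(cells)
        assert table.p("interaction") == pytest.approx(0.729, abs=0.05)

    def test_weight_day45_row_shows_diabetes_effect(self):
        cells = {(False, False): SummaryCell(310, 28, 9),
                 (False, True): SummaryCell(322, 35, 7),
                 (True, False): SummaryCell(275, 53, 9),
                 (True, True): SummaryCell(223, 71, 5)}
        table = anova_from_summary(cells)
        assert table.p("diabetes") < 0.001

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary({(False, False): SummaryCell(1, 1, 3)})


class TestSNK:
    def test_two_groups_coincide_with_pooled_t_test(self):
        for seed in range(60):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 8)
            b = rng.normal(0.9, 1.0, 6)
            df = pd.DataFrame({"group": ["a"] * 8 + ["b"] * 6,
                               "y": np.concatenate([a, b])})
            snk = snk_posthoc(df, "y").loc["a", "b"]
            t = sps.ttest_ind(a, b).pvalue < 0.05
            assert snk == t

    def test_extreme_separation_makes_all_pairs_significant(self):
        rng = np.random.default_rng(4)
        rows = []
        for i, mu in enumerate([0.0, 10.0, 20.0, 30.0]):
            for v in rng.normal(mu, 1.0, 6):
                rows.append({"group": f"g{i}", "y": v})
        sig = snk_posthoc(pd.DataFrame(rows), "y")
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert sig.iloc[i, j]

    def test_identical_groups_have_no_significant_pairs(self):
        rows = [{"group": f"g{i}", "y": v}
                for i in range(4) for v in (1.0, 2.0, 3.0)]
        sig = snk_posthoc(pd.DataFrame(rows), "y")
        assert not sig.to_numpy().any()

    def test_no_significant_pair_inside_non_significant_span(self):
        # coherence property over random data
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            rows = []
            for i, mu in enumerate(rng.normal(0.0, 1.5, 4)):
                for v in rng.normal(mu, 1.0, rng.integers(4, 9)):
                    rows.append({"group": f"g{i}", "y": v})
            df = pd.DataFrame(rows)
            sig = snk_posthoc(df, "y")
            means = df.groupby("group")["y"].mean().sort_values()
            order = means.index.to_list()
            for lo in range(4):
                for hi in range(lo + 1, 4):
                    if not sig.loc[order[lo], order[hi]]:
                        inner = order[lo:hi + 1]
                        for gi in inner:
                            for gj in inner:
                                assert not sig.loc[gi, gj]

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": ["only"] * 4, "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            snk_posthoc(df, "y")


class TestTransforms:
    def test_log_transform_closed_forms(self):
        df = pd.DataFrame({"animal_id": ["a", "b", "c"],
                           "albumin": [1.0, np.e, np.e ** 2]})
        out = log_transform_outcome(df, "albumin")
        np.testing.assert_allclose(out["albumin"], [0.0, 1.0, 2.0])
        assert df["albumin"].iloc[0] == 1.0  # input untouched

    def test_non_positive_value_error_names_the_animal(self):
        df = pd.DataFrame({"animal_id": ["a", "bad-rat"],
                           "albumin": [1.0, 0.0]})
        with pytest.raises(ValueError, match="bad-rat"):
            log_transform_outcome(df, "albumin")

    def test_log_transform_improves_normality_of_lognormal_data(self):
        hits_raw = hits_log = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(5.0, 0.9, 20)
            hits_raw += sps.shapiro(x).pvalue > 0.05
            hits_log += sps.shapiro(np.log(x)).pvalue > 0.05
        assert hits_log > hits_raw

    def test_densitometry_normalization_closed_form(self):
        out = normalize_densitometry([2.0, 4.0, 6.0],
                                     [True, True, False])
        np.testing.assert_allclose(out, [66.666667, 133.333333, 200.0],
                                   rtol=1e-6)

    def test_densitometry_all_equal_gives_100(self):
        out = normalize_densitometry([5.0, 5.0, 5.0], [True, False, True])
        np.testing.assert_allclose(out, 100.0)

    def test_densitometry_batches_are_independent(self):
        values = [2.0, 6.0, 10.0, 30.0]
        flags = [True, False, True, False]
        batches = [0, 0, 1, 1]
        out = normalize_densitometry(values, flags, batches)
        np.testing.assert_allclose(out, [100.0, 300.0, 100.0, 300.0])

    def test_densitometry_batch_without_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_densitometry([1.0, 2.0], [False, False])


class TestDerivedArithmetic:
    def test_percent_difference_heart_rate_increase(self):
        assert round(percent_difference(384.82, 431.32)) == 12

    def test_percent_difference_heart_rate_decrease(self):
        assert round(percent_difference(384.82, 316.21)) == -18

    def test_percent_difference_identity(self):
        assert percent_difference(123.4, 123.4) == 0.0

    def test_percent_difference_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_difference(0.0, 1.0)

    def test_fold_change_sapv_reduction(self):
        fold = fold_change(68.33, 15.61, direction="reduction")
        assert fold == pytest.approx(4.377, abs=0.001)
        assert round(fold) == 4

    def test_fold_change_glycemia_elevation(self):
        assert fold_change(92.0, 417.5, direction="elevation") == \
            pytest.approx(4.54, abs=0.01)

    def test_fold_change_equal_inputs(self):
        assert fold_change(3.3, 3.3) == pytest.approx(1.0)

    def test_fold_change_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 2.0)

    def test_pooled_summary_baseline_weight(self):
        cells = [SummaryCell(258, 14, 9), SummaryCell(267, 29, 7),
                 SummaryCell(269, 13, 9), SummaryCell(272, 28, 5)]
        grand, pooled = pooled_summary(cells)
        assert round(grand) == 266
        assert round(pooled) == 21

    def test_pooled_summary_repeated_cell_is_identity(self):
        cells = [SummaryCell(100.0, 7.0, 6)] * 3
        grand, pooled = pooled_summary(cells)
        assert grand == pytest.approx(100.0)
        assert pooled == pytest.approx(7.0)
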