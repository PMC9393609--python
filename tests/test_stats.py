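import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from alpspipe.stats import (
    GroupSummary,
    bonferroni_threshold,
    build_comparison_table,
    categorical_test,
    comparison_rows_to_frame,
    pearson_correlation,
    summary_table,
    t_test_from_summary,
    t_test_on_samples,
    welch_t_test,
)


class TestTTestFromSummary:
    def test_published_alps_group_comparison(self):
        """The headline two-group ALPS comparison from its summary cells."""
        res = t_test_from_summary(
            GroupSummary(1.2594, 0.1994, 18), GroupSummary(1.4777, 0.2327, 18)
        )
        assert res.df == 34
        assert res.t == pytest.approx(-3.022, abs=5e-4)
        assert res.p == pytest.approx(0.0048, abs=1e-4)
        # agrees with scipy's summary-statistics Student t
        ref = sps.ttest_ind_from_stats(1.2594, 0.1994, 18,
                                       1.4777, 0.2327, 18, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_summaries_give_null_result(self):
        g = GroupSummary(1.0, 0.2, 10)
        res = t_test_from_summary(g, g)
        assert res.t == 0.0 and res.p == 1.0

    def test_published_dm_subgroup_comparison(self):
        res = t_test_from_summary(
            GroupSummary(1.2004, 0.2321, 8), GroupSummary(1.3067, 0.1662, 10)
        )
        assert res.df == 16
        assert round(res.p, 4) == 0.2738

    def test_zero_variance_cases(self):
        a = GroupSummary(1.0, 0.0, 5)
        assert t_test_from_summary(a, GroupSummary(1.0, 0.0, 5)).p == 1.0
        with pytest.raises(ValueError):
            t_test_from_summary(a, GroupSummary(2.0, 0.0, 5))

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1.0, 0.1, 1)


class TestTTestOnSamples:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        res = t_test_on_samples(x, list(x))
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_computed_pooled_t(self):
        res = t_test_on_samples([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            t_test_on_samples([1.0], [1.0, 2.0])

    def test_agrees_with_summary_route_on_random_pairs(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 30))
            y = rng.normal(loc=0.3, size=rng.integers(2, 30))
            a = t_test_on_samples(x, y)
            b = t_test_from_summary(GroupSummary.of(x), GroupSummary.of(y))
            assert a.t == pytest.approx(b.t, abs=1e-12)
            assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_swapping_groups_negates_t_and_preserves_p(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.5, size=9)
        a, b = t_test_on_samples(x, y), t_test_on_samples(y, x)
        assert a.t == pytest.approx(-b.t, abs=1e-14)
        assert a.p == b.p
        assert 0.0 <= a.p <= 1.0


class TestCategoricalTest:
    def test_balanced_table_is_null(self):
        res = categorical_test([[10, 10], [10, 10]])
        assert res.method == "chi-square"
        assert res.statistic == 0.0 and res.p == 1.0

    def test_sex_distribution_comparison(self):
        # 9/18 vs 11/18 males: uncorrected chi-square
        res = categorical_test([[9, 9], [11, 7]])
        assert res.method == "chi-square"
        assert res.statistic == pytest.approx(0.45, abs=1e-12)
        assert res.p == pytest.approx(0.502, abs=5e-4)

    def test_sparse_table_falls_back_to_fisher(self):
        res = categorical_test([[3, 0], [0, 3]])
        assert res.method == "fisher"
        # exhaustive hypergeometric: only 2 of C(6,3)=20 splits this extreme
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[3, -1], [2, 2]])


class TestPearsonCorrelation:
    def test_perfect_positive_linear_relation(self):
        x = np.arange(1.0, 9.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative_relation(self):
        x = np.arange(1.0, 9.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_example(self):
        res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        # p from t = r sqrt((n-2)/(1-r^2)) = 0.8 sqrt(2/0.36) = 1.8856 on 2 df
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert t == pytest.approx(1.8856, abs=1e-4)
        assert res.p == pytest.approx(2 * sps.t.sf(t, 2), abs=1e-12)
        assert res.p == pytest.approx(0.2, abs=1e-9)
        assert res.n == 4

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    def test_invariance_under_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(99)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = pearson_correlation(x, y)
        pos = pearson_correlation(a * x + b, y)
        assert pos.r == pytest.approx(base.r, abs=1e-9)
        neg = pearson_correlation(-a * x + b, y)
        assert neg.r == pytest.approx(-base.r, abs=1e-9)


class TestBonferroni:
    def test_single_comparison_is_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_nine_comparisons_truncates_to_printed_threshold(self):
        thr = bonferroni_threshold(0.05, 9)
        assert thr == pytest.approx(0.05 / 9, abs=1e-15)
        assert int(thr * 1e4) / 1e4 == 0.0055

    def test_five_comparisons(self):
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestComparisonTable:
    def _frame(self, delta=0.0):
        rng = np.random.default_rng(4)
        n = 8
        rows = []
        for grp, shift in (("a", 0.0), ("b", delta)):
            for i in range(n):
                rows.append({
                    "subject_id": f"{grp}{i}", "group": grp,
                    "m1": rng.normal(1.0 + shift, 0.1),
                    "alps_index": rng.normal(1.3 + shift, 0.1),
                })
        return pd.DataFrame(rows)

    def test_identical_groups_have_unit_p_and_no_flags(self):
        df = self._frame()
        half = df[df.group == "a"].copy()
        half["group"] = "b"
        dup = pd.concat([df[df.group == "a"], half], ignore_index=True)
        rows = build_comparison_table(
            dup, ["m1", "alps_index"], group_col="group", groups=("a", "b"),
        )
        for r in rows:
            assert r.test.p == 1.0 and not r.significant

    def test_alps_row_uses_raw_alpha_and_others_corrected(self):
        rows = build_comparison_table(
            self._frame(0.5), ["m1", "alps_index"], group_col="group",
            groups=("a", "b"), alpha=0.05, m=9,
        )
        by_name = {r.measure: r for r in rows}
        assert by_name["m1"].threshold == pytest.approx(0.05 / 9)
        assert by_name["alps_index"].threshold == 0.05

    def test_welch_flag_switches_the_row_test(self):
        df = self._frame(0.3)
        pooled = build_comparison_table(df, ["m1"], group_col="group",
                                        groups=("a", "b"))
        welch = build_comparison_table(df, ["m1"], group_col="group",
                                       groups=("a", "b"), welch=True)
        assert pooled[0].test.df == 14
        assert welch[0].test.df < 14
        assert welch[0].test.t == pytest.approx(pooled[0].test.t)  # equal n

    def test_missing_measure_error_names_subject(self):
        df = self._frame()
        df.loc[df.index[3], "m1"] = np.nan
        sid = df.loc[df.index[3], "subject_id"]
        with pytest.raises(ValueError, match=str(sid)):
            build_comparison_table(df, ["m1"], group_col="group",
                                   groups=("a", "b"))

    def test_frame_round_trip_has_4dp_p_column(self):
        rows = build_comparison_table(
            self._frame(0.2), ["m1", "alps_index"], group_col="group",
            groups=("a", "b"),
        )
        frame = comparison_rows_to_frame(rows)
        assert np.allclose(frame["p_4dp"], frame["p"].round(4))


def test_summary_table_round_trips_group_cells():
    df = pd.DataFrame([
        {"measure": "alps_index", "mean1": 1.2594, "sd1": 0.1994, "n1": 18,
         "mean2": 1.4777, "sd2": 0.2327, "n2": 18},
    ])
    out = summary_table(df, alpha=0.05, m=1)
    assert out.loc[0, "df"] == 34
    assert out.loc[0, "p"] == pytest.approx(0.00474, abs=5e-5)
    assert bool(out.loc[0, "significant"])


def test_welch_is_available_for_sensitivity_checks():
    res = welch_t_test(
        GroupSummary(1.2594, 0.1994, 18), GroupSummary(1.4777, 0.2327, 18)
    )
    # same t as pooled at equal n, heavier-tailed df
    assert res.t == pytest.approx(-3.0223, abs=1e-4)
    assert res.df < 34
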