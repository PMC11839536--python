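"""Welch, ROUT, Šídák, two-way and nested ANOVA behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from glymphkin.group_stats import (
    compare_conditions,
    nested_anova,
    rout_outliers,
    sidak_adjust,
    two_way_anova,
    welch_t_test,
)


class TestWelch:
    def test_identical_groups_t_zero_p_one(self):
        r = welch_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_hand_computed_example(self):
        # both variances 1, se = sqrt(2/3), diff = -10 -> t = -12.247, df = 4
        r = welch_t_test([10, 11, 12], [20, 21, 22])
        assert r.statistic == pytest.approx(-12.247, abs=1e-3)
        assert r.df == pytest.approx(4.0, abs=1e-12)

    def test_swapping_groups_negates_t_only(self):
        x, y = [3.0, 5.0, 9.0, 4.0], [7.0, 7.5, 10.0]
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p_raw == pytest.approx(b.p_raw, rel=1e-12)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(0, rng.uniform(0.5, 3), rng.integers(2, 20))
            y = rng.normal(rng.uniform(-1, 1), 1, rng.integers(2, 20))
            ours = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.df == pytest.approx(ref.df, abs=1e-9)
            assert ours.p_raw == pytest.approx(ref.pvalue, abs=1e-9)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])


class TestROUT:
    def test_tight_cluster_clean(self):
        _, flags = rout_outliers([1.0, 1.1, 0.9, 1.05, 0.95], q=1.0)
        assert not flags.any()

    def test_flags_exactly_the_planted_extreme(self):
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 10.0]
        kept, flags = rout_outliers(values, q=1.0)
        assert list(flags) == [False] * 5 + [True]
        assert 10.0 not in kept

    @given(
        a=st.floats(0.1, 50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_affine_equivariance(self, a, b, sign):
        rng = np.random.default_rng(17)
        values = np.append(rng.normal(0, 1, 12), 9.0)
        _, flags = rout_outliers(values, q=1.0)
        _, flags2 = rout_outliers(sign * a * values + b, q=1.0)
        assert np.array_equal(flags, flags2)

    def test_identical_values_no_outliers(self):
        _, flags = rout_outliers([2.0] * 6, q=1.0)
        assert not flags.any()

    def test_q_bounds_enforced(self):
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0, 3.0], q=0.0)
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0], q=1.0)

    def test_false_flag_rate_controlled_on_clean_gaussians(self):
        """At Q = 1% the per-point false-flag rate on clean normal samples
        stays well under control (spot check, 2000 reps)."""
        rng = np.random.default_rng(5)
        flagged = total = 0
        for _ in range(2000):
            values = rng.normal(0, 1, 20)
            _, flags = rout_outliers(values, q=1.0)
            flagged += flags.sum()
            total += 20
        assert flagged / total < 0.025


class TestSidak:
    def test_single_comparison_identity(self):
        assert sidak_adjust([0.05], 1)[0] == pytest.approx(0.05, rel=1e-12)

    def test_direct_evaluation(self):
        assert sidak_adjust([0.01], 3)[0] == pytest.approx(0.029701, abs=1e-9)

    def test_p_one_stays_one(self):
        assert sidak_adjust([1.0], 7)[0] == 1.0

    @given(
        p=st.floats(0.0, 1.0),
        q=st.floats(0.0, 1.0),
        m=st.integers(1, 50),
    )
    def test_monotone_in_p_and_m(self, p, q, m):
        lo, hi = sorted([p, q])
        a = sidak_adjust([lo, hi], m + 1)
        assert a[0] <= a[1]
        assert sidak_adjust([p], m + 1)[0] >= sidak_adjust([p], m)[0] - 1e-15


def balanced_table(effect_a=0.0, effect_b=0.0, interaction=0.0, noise=1.0,
                   reps=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in enumerate(("sham", "tbi")):
        for j, b in enumerate(("FC", "LLV", "PPC")):
            for _ in range(reps):
                y = (
                    effect_a * i + effect_b * j + interaction * i * j
                    + rng.normal(0, noise)
                )
                rows.append({"condition": a, "level": b, "y": y})
    return pd.DataFrame(rows)


def manual_two_way_ss(df, a_col, b_col, y_col):
    """Independent balanced two-way SS decomposition."""
    grand = df[y_col].mean()
    n = len(df)
    a_means = df.groupby(a_col)[y_col].mean()
    b_means = df.groupby(b_col)[y_col].mean()
    cell_means = df.groupby([a_col, b_col])[y_col].mean()
    counts_a = df.groupby(a_col).size()
    counts_b = df.groupby(b_col).size()
    counts_cell = df.groupby([a_col, b_col]).size()
    ss_a = float((counts_a * (a_means - grand) ** 2).sum())
    ss_b = float((counts_b * (b_means - grand) ** 2).sum())
    ss_cells = float((counts_cell * (cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    resid = df[y_col] - cell_means.loc[
        pd.MultiIndex.from_frame(df[[a_col, b_col]])
    ].to_numpy()
    ss_resid = float((resid**2).sum())
    return ss_a, ss_b, ss_ab, ss_resid


class TestTwoWayAnova:
    def test_all_equal_observations_give_zero_f(self):
        df = balanced_table(noise=0.0)
        df["y"] = 5.0
        results = two_way_anova(df, "condition", "level", "y", posthoc="none")
        assert all(r.statistic == 0.0 and r.p_raw == 1.0 for r in results)

    def test_additive_shift_matches_ss_oracle(self):
        df = balanced_table(effect_a=2.0, noise=1.0, seed=3)
        results = {
            r.comparison: r
            for r in two_way_anova(df, "condition", "level", "y", posthoc="none")
        }
        ss_a, ss_b, ss_ab, ss_resid = manual_two_way_ss(df, "condition", "level", "y")
        df_resid = len(df) - 6
        f_a = (ss_a / 1) / (ss_resid / df_resid)
        p_a = float(sps.f.sf(f_a, 1, df_resid))
        main = results["anova:condition"]
        assert main.statistic == pytest.approx(f_a, abs=1e-9)
        assert main.p_raw == pytest.approx(p_a, abs=1e-9)
        inter = results["anova:interaction"]
        f_ab = (ss_ab / 2) / (ss_resid / df_resid)
        assert inter.statistic == pytest.approx(f_ab, abs=1e-9)

    def test_null_permutation_p_values_uniform(self):
        """Main-effect p-values under label permutation are ~Uniform(0,1)."""
        rng = np.random.default_rng(8)
        df = balanced_table(noise=1.0, seed=9)
        labels = df["condition"].to_numpy().copy()
        p_values = []
        df_resid = len(df) - 6
        for _ in range(1000):
            rng.shuffle(labels)
            df["condition"] = labels
            ss_a, _, _, ss_resid = manual_two_way_ss(df, "condition", "level", "y")
            f = (ss_a / 1) / (ss_resid / df_resid)
            p_values.append(float(sps.f.sf(f, 1, df_resid)))
        ks = sps.kstest(p_values, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_cell_named(self):
        df = balanced_table()
        df = df[~((df["condition"] == "tbi") & (df["level"] == "PPC"))]
        with pytest.raises(ValueError, match="tbi.*PPC"):
            two_way_anova(df, "condition", "level", "y")

    def test_sidak_and_tukey_posthoc_adjusted_not_below_raw(self):
        df = balanced_table(effect_a=1.0, interaction=0.5, seed=5)
        for method in ("sidak", "tukey"):
            for r in two_way_anova(df, "condition", "level", "y", posthoc=method):
                assert r.p_adjusted >= r.p_raw - 1e-12


def nested_table(shift=0.0, animal_sd=1.0, within_sd=0.5, n_animals=5,
                 reps=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, cond in enumerate(("sham", "tbi")):
        for a in range(n_animals):
            mean = shift * i + rng.normal(0, animal_sd)
            for _ in range(reps):
                rows.append(
                    {
                        "condition": cond,
                        "animal": f"{cond}{a}",
                        "y": mean + rng.normal(0, within_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestNestedAnova:
    def test_duplicating_measurements_leaves_f_unchanged(self):
        df = nested_table(shift=1.0, seed=2)
        doubled = pd.concat([df, df], ignore_index=True)
        f1 = nested_anova(df, "condition", "animal", "y", posthoc="none")[0]
        f2 = nested_anova(doubled, "condition", "animal", "y", posthoc="none")[0]
        assert f1.statistic == pytest.approx(f2.statistic, rel=1e-12)
        assert f1.df == f2.df

    def test_balanced_two_groups_f_equals_t_squared_on_animal_means(self):
        df = nested_table(shift=0.8, seed=4)
        res = nested_anova(df, "condition", "animal", "y", posthoc="none")[0]
        means = df.groupby(["condition", "animal"])["y"].mean()
        t = sps.ttest_ind(means["sham"], means["tbi"], equal_var=True)
        assert res.statistic == pytest.approx(t.statistic**2, abs=1e-9)

    def test_clear_separation_is_significant(self):
        df = nested_table(shift=10.0, animal_sd=0.01, within_sd=0.01, seed=6)
        res = nested_anova(df, "condition", "animal", "y", posthoc="none")[0]
        assert res.p_raw < 0.001

    def test_single_animal_condition_rejected(self):
        df = nested_table()
        df = df[~((df["condition"] == "tbi") & (df["animal"] != "tbi0"))]
        with pytest.raises(ValueError, match="single animal"):
            nested_anova(df, "condition", "animal", "y")

    def test_tukey_posthoc_matches_statsmodels_on_animal_means(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = nested_table(shift=1.2, seed=7)
        res = nested_anova(df, "condition", "animal", "y", posthoc="tukey")
        pair = [r for r in res if "animal means" in r.comparison][0]
        means = df.groupby(["condition", "animal"])["y"].mean().reset_index()
        ref = pairwise_tukeyhsd(means["y"], means["condition"])
        assert pair.p_adjusted == pytest.approx(float(ref.pvalues[0]), abs=1e-6)


class TestCompareConditions:
    def metrics_table(self, sham, tbi, roi="FC", metric="appearance_time"):
        rows = []
        for i, v in enumerate(sham):
            rows.append({"animal_id": f"s{i}", "condition": "sham",
                         "roi_name": roi, metric: v,
                         "censored": v is None})
        for i, v in enumerate(tbi):
            rows.append({"animal_id": f"t{i}", "condition": "tbi",
                         "roi_name": roi, metric: v,
                         "censored": v is None})
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        table = self.metrics_table([5.0, 6.0, 7.0, 8.0], [5.0, 6.0, 7.0, 8.0])
        res = compare_conditions(table, "appearance_time", ["FC"])
        assert res[0].p_raw == 1.0

    def test_rout_is_noop_on_clean_data(self):
        rng = np.random.default_rng(13)
        sham = list(rng.normal(10, 0.5, 10))
        tbi = list(rng.normal(12, 0.5, 10))
        table = self.metrics_table(sham, tbi)
        with_rout = compare_conditions(table, "appearance_time", ["FC"], q=1.0)
        without = compare_conditions(table, "appearance_time", ["FC"], q=None)
        assert with_rout[0].p_raw == pytest.approx(without[0].p_raw, rel=1e-12)
        assert not with_rout[0].outliers_removed

    def test_censored_values_excluded_and_counted(self):
        table = self.metrics_table([5.0, 6.0, None, 7.0], [9.0, 10.0, 11.0])
        res = compare_conditions(table, "appearance_time", ["FC"], q=None)
        assert res[0].n_per_group == {"sham": 3, "tbi": 3}
        assert res[0].extra["censored"] == {"sham": 1, "tbi": 0}

    def test_too_few_values_reported_not_dropped(self):
        table = self.metrics_table([5.0, None, None, None], [9.0, 10.0, 11.0])
        res = compare_conditions(table, "appearance_time", ["FC"], q=None)
        assert math.isnan(res[0].p_raw)
        assert "not computable" in res[0].extra["status"]
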