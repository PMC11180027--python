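"""Holm correction, ANOVA battery, nonparametric branch and power analysis."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from neuroforage.stats import (anova_power, anova_power_n, correlation_holm,
                               friedman_wilcoxon, holm_adjust, linear_regression,
                               mixed_anova, one_way_error_df, posthoc_holm,
                               shapiro_gate)


class TestHolm:
    def test_hand_computed_example(self):
        assert np.allclose(holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_never_decreases_and_preserves_order(self, rng):
        p = rng.random(20)
        adj = holm_adjust(p)
        assert (adj >= p).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels(self, rng):
        p = rng.random(15)
        ours = holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(ours, ref)


class TestShapiroGate:
    def test_normal_sample_routes_parametric(self, rng):
        d = shapiro_gate(rng.normal(0, 1, 500))
        assert d.branch == "parametric" and d.normal

    def test_constant_sample_fails(self):
        d = shapiro_gate(np.full(10, 3.0))
        assert not d.normal and d.branch == "nonparametric"

    def test_heavy_tails_fail_overwhelmingly(self):
        rng = np.random.default_rng(0)
        fails = sum(not shapiro_gate(rng.standard_cauchy(100)).normal
                    for _ in range(50))
        assert fails >= 48

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])


def balanced_table(rng, a=3, n=6, b=3, group_shift=0.0):
    rows = []
    for gi in range(a):
        for s in range(n):
            subj_eff = rng.normal(0, 0.5)
            for bi in range(b):
                rows.append({"rat_id": f"g{gi}s{s}", "group": f"g{gi}",
                             "bin": f"b{bi}",
                             "value": rng.normal(group_shift * gi, 1.0) + subj_eff})
    return pd.DataFrame(rows)


def split_plot_oracle(df):
    """Hand-computed sums of squares for a balanced split-plot design."""
    a = df["group"].nunique()
    b = df["bin"].nunique()
    n = df["rat_id"].nunique() // a
    grand = df["value"].mean()
    mean_a = df.groupby("group")["value"].mean()
    mean_b = df.groupby("bin")["value"].mean()
    mean_ab = df.groupby(["group", "bin"])["value"].mean()
    mean_s = df.groupby("rat_id")["value"].mean()
    group_of = df.groupby("rat_id")["group"].first()
    ss_a = n * b * ((mean_a - grand) ** 2).sum()
    ss_subj = b * ((mean_s - mean_a[group_of].to_numpy()) ** 2).sum()
    ss_b = a * n * ((mean_b - grand) ** 2).sum()
    ss_ab = n * sum(
        (mean_ab[g, bb] - mean_a[g] - mean_b[bb] + grand) ** 2
        for g in mean_a.index for bb in mean_b.index)
    ss_tot = ((df["value"] - grand) ** 2).sum()
    ss_err2 = ss_tot - ss_a - ss_subj - ss_b - ss_ab
    f_a = (ss_a / (a - 1)) / (ss_subj / (a * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_err2 / (a * (n - 1) * (b - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_err2 / (a * (n - 1) * (b - 1)))
    return {"group": f_a, "bin": f_b, "Interaction": f_ab}


class TestMixedAnova:
    def test_agrees_with_sums_of_squares_oracle(self, rng):
        df = balanced_table(rng, group_shift=0.8)
        oracle = split_plot_oracle(df)
        results = {r.effect: r for r in mixed_anova(
            df, dv="value", between="group", within="bin", subject="rat_id",
            gg_correct=False)}
        for effect, f_expected in oracle.items():
            assert results[effect].F == pytest.approx(f_expected, abs=1e-6)

    def test_identical_groups_give_tiny_f(self, rng):
        df = balanced_table(rng)
        # copy group g0's values onto every group, subject by subject
        wide = df.pivot(index="rat_id", columns="bin", values="value")
        base = wide.loc[[f"g0s{s}" for s in range(6)]].to_numpy()
        for gi in range(3):
            for s in range(6):
                wide.loc[f"g{gi}s{s}"] = base[s]
        df2 = wide.reset_index().melt("rat_id", var_name="bin", value_name="value")
        df2["group"] = df2["rat_id"].str[:2]
        res = {r.effect: r for r in mixed_anova(
            df2, dv="value", between="group", within="bin", subject="rat_id",
            gg_correct=False)}
        assert res["group"].F == pytest.approx(0.0, abs=1e-10)

    def test_gg_correction_shrinks_dfs_within_bounds(self, rng):
        df = balanced_table(rng, b=4)
        res = {r.effect: r for r in mixed_anova(
            df, dv="value", between="group", within="bin", subject="rat_id",
            gg_correct=True)}
        b = 4
        eps = res["bin"].df1 / (b - 1)
        assert 1.0 / (b - 1) - 1e-9 <= eps <= 1.0 + 1e-9
        assert res["bin"].correction == "Greenhouse-Geisser"
        assert res["bin"].df1 != int(res["bin"].df1) or eps == 1.0

    def test_incomplete_subject_dropped_with_warning(self, rng):
        df = balanced_table(rng)
        df = df[~((df["rat_id"] == "g0s0") & (df["bin"] == "b2"))]
        with pytest.warns(UserWarning, match="g0s0"):
            res = mixed_anova(df, dv="value", between="group", within="bin",
                              subject="rat_id", gg_correct=False)
        assert len(res) == 3


class TestPosthoc:
    def test_single_pair_unadjusted(self, rng):
        df = pd.DataFrame({"group": ["a"] * 8 + ["b"] * 8,
                           "value": rng.normal(0, 1, 16)})
        out = posthoc_holm(df, dv="value", group="group")
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_warns_without_omnibus(self, rng):
        df = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5,
                           "value": rng.normal(0, 1, 10)})
        with pytest.warns(UserWarning, match="omnibus"):
            posthoc_holm(df, dv="value", group="group",
                         omnibus_significant=False)


class TestFriedman:
    def test_identical_conditions_not_significant(self):
        wide = pd.DataFrame({"c1": [1.0, 2, 3], "c2": [1.0, 2, 3],
                             "c3": [1.0, 2, 3]})
        res = friedman_wilcoxon(wide)
        assert res["p"] == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        wide = pd.DataFrame(rng.normal(0, 1, (20, 3)),
                            columns=["c1", "c2", "c3"])
        wide["c3"] += 10
        res = friedman_wilcoxon(wide)
        assert res["p"] < 1e-4
        ph = res["posthoc"].set_index(["A", "B"])
        assert ph.loc[("c1", "c3"), "p_adj"] < 0.01

    def test_rank_invariance_under_monotone_transform(self, rng):
        wide = pd.DataFrame(rng.normal(2, 1, (15, 3)),
                            columns=["c1", "c2", "c3"])
        a = friedman_wilcoxon(wide)
        b = friedman_wilcoxon(np.exp(wide))
        assert a["chi2"] == pytest.approx(b["chi2"])
        assert a["p"] == pytest.approx(b["p"])

    def test_incomplete_blocks_rejected(self):
        wide = pd.DataFrame({"c1": [1.0, np.nan], "c2": [1.0, 2],
                             "c3": [2.0, 1]})
        with pytest.raises(ValueError, match="complete blocks"):
            friedman_wilcoxon(wide)


class TestCorrelation:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(0, 1, 100)
        table = pd.DataFrame({"x": x, "y": 2 * x, "z": rng.normal(0, 1, 100)})
        cm = correlation_holm(table)
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert (np.diag(cm.r) == 1.0).all()
        assert np.allclose(cm.r, cm.r.T)
        assert np.allclose(cm.p_adj, cm.p_adj.T)

    def test_independent_columns_uncorrelated(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (1000, 3)),
                             columns=["a", "b", "c"])
        cm = correlation_holm(table)
        off = cm.r.to_numpy()[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.1).all()


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = linear_regression(x, 3 * x - 2)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(-2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_shuffled_has_no_relation(self, rng):
        x = rng.normal(0, 1, 1000)
        y = rng.permutation(2 * x)
        assert linear_regression(x, y).r_squared < 0.01

    def test_r_squared_is_squared_pearson(self, rng):
        x, y = rng.normal(0, 1, (2, 50))
        from scipy.stats import pearsonr
        res = linear_regression(x, y)
        assert res.r_squared == pytest.approx(pearsonr(x, y)[0] ** 2)


class TestPower:
    def test_study_design_needs_five_per_group(self):
        # f = 0.8, five groups, alpha .05, power .8 -> n = 5
        assert anova_power_n(0.8, 5) == 5

    def test_power_monotone_in_n(self):
        powers = [anova_power(0.5, 4, n) for n in range(2, 30)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_vanishing_effect_approaches_alpha(self):
        assert anova_power(1e-9, 5, 50, alpha=0.05) == pytest.approx(0.05, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            anova_power_n(0.0, 5)
        with pytest.raises(ValueError):
            anova_power_n(0.5, 5, alpha=0.9, power=0.8)


def test_one_way_error_df():
    assert one_way_error_df([9, 6, 30, 7, 21]) == 68
    assert one_way_error_df([5] * 5) == 20
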