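"""Outlier rule, sham reference, the affected criterion and data reduction."""

import numpy as np
import pandas as pd
import pytest

from neuroforage.phenotype import (DEFAULT_WINDOWS, ShamReference,
                                   assign_behavioural_groups, bin_weekly,
                                   classify_affected, classify_cohort,
                                   cohort_phenotype_counts, daily_measure_table,
                                   expected_null_count, null_false_affected_rate,
                                   remove_outliers, sham_reference)


def tidy(rows):
    return pd.DataFrame(rows, columns=["rat_id", "group", "day", "measure", "value"])


def cell(values, group="g", day=1, measure="m"):
    return tidy([(f"r{i}", group, day, measure, v) for i, v in enumerate(values)])


class TestRemoveOutliers:
    def test_degenerate_iqr_removes_extreme(self):
        # mean 2.8, IQR 0 -> cutoff 2.8, the 10 is removed
        out, report = remove_outliers(cell([1, 1, 1, 1, 10]))
        assert out["value"].isna().sum() == 1
        assert report.iloc[0]["value"] == 10
        assert report.iloc[0]["cutoff"] == pytest.approx(2.8)

    def test_moderate_spread_keeps_all(self):
        # mean 3, IQR 2 -> cutoff 9, nothing above
        out, report = remove_outliers(cell([1, 2, 3, 4, 5]))
        assert out["value"].notna().all() and len(report) == 0

    def test_identical_values_untouched(self):
        out, report = remove_outliers(cell([4, 4, 4, 4]))
        assert out["value"].notna().all() and len(report) == 0

    def test_cells_are_independent(self):
        table = pd.concat([cell([1, 1, 1, 1, 10], day=1),
                           cell([10, 10, 10, 10, 10], day=2)])
        out, report = remove_outliers(table)
        assert len(report) == 1 and report.iloc[0]["day"] == 1


class TestShamReference:
    def test_hand_computed_mean_sd_threshold(self):
        table = tidy([("s1", "sham_vehicle", 1, "tica_per_entry", 10.0),
                      ("s2", "sham_vehicle", 1, "tica_per_entry", 14.0)])
        ref = sham_reference(table, "vehicle")
        assert ref.mean[1] == pytest.approx(12.0)
        assert ref.sd[1] == pytest.approx(2.8284, abs=1e-3)  # sample SD, n-1
        assert ref.threshold_on(1) == pytest.approx(20.485, abs=1e-2)

    def test_equal_sham_values_threshold_equals_mean(self):
        table = tidy([("s1", "sham_vehicle", 1, "tica_per_entry", 5.0),
                      ("s2", "sham_vehicle", 1, "tica_per_entry", 5.0)])
        assert sham_reference(table, "vehicle").threshold_on(1) == 5.0

    def test_single_sham_day_skipped_with_warning(self):
        table = tidy([("s1", "sham_vehicle", 1, "tica_per_entry", 5.0)])
        with pytest.warns(UserWarning, match="<2 sham"):
            ref = sham_reference(table, "vehicle")
        assert ref.threshold_on(1) is None

    def test_treatment_arm_matching(self):
        # minocycline-treated CCI rats are referenced to the minocycline shams
        rows = []
        for day in range(1, 13):
            for i in range(3):
                rows.append((f"sv{i}", "sham_vehicle", day, "tica_per_entry", 5.0 + i))
                rows.append((f"sm{i}", "sham_minocycline", day, "tica_per_entry", 50.0 + i))
            rows.append(("cm0", "cci_minocycline", day, "tica_per_entry", 20.0))
        calls = classify_cohort(tidy(rows))
        # 20 would exceed the vehicle-sham threshold but not the minocycline one
        call = next(c for c in calls if c.rat_id == "cm0")
        assert call.affected is False
        assert call.exceedance_days[0] == 0


def flat_reference(threshold, days=range(1, 19)):
    # mean = threshold, SD = 0
    return ShamReference("vehicle", mean={d: threshold for d in days},
                         sd={d: 0.0 for d in days})


class TestClassifyAffected:
    def test_exactly_at_threshold_is_not_exceedance(self):
        ref = flat_reference(10.0)
        call = classify_affected({d: 10.0 for d in range(1, 19)}, ref)
        assert call.affected is False
        assert call.exceedance_days == (0, 0, 0)

    def test_three_days_in_each_window_is_affected(self):
        ref = flat_reference(10.0)
        daily = {d: 5.0 for d in range(1, 19)}
        daily.update({1: 11, 2: 11, 3: 11, 7: 11, 8: 11, 9: 11})
        call = classify_affected(daily, ref)
        assert call.affected is True
        assert call.exceedance_days[:2] == (3, 3)

    def test_second_window_failure_means_unaffected(self):
        ref = flat_reference(10.0)
        daily = {d: 5.0 for d in range(1, 19)}
        daily.update({d: 11 for d in range(1, 7)})   # all 6 days of window 1
        daily.update({7: 11, 8: 11})                 # only 2 days of window 2
        call = classify_affected(daily, ref)
        assert call.affected is False
        assert call.exceedance_days[:2] == (6, 2)

    def test_insufficient_days_is_indeterminate(self):
        ref = flat_reference(10.0)
        call = classify_affected({1: 11.0, 2: 11.0}, ref)
        assert call.affected is None

    def test_brute_force_enumeration_of_rule(self):
        # every pattern of exceedances over the two 6-day windows
        ref = flat_reference(0.0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            flags = rng.random(12) < 0.4
            daily = {d: (1.0 if flags[d - 1] else -1.0) for d in range(1, 13)}
            call = classify_affected(daily, ref, windows=DEFAULT_WINDOWS[:2])
            expected = flags[:6].sum() >= 3 and flags[6:].sum() >= 3
            assert call.affected == expected

    def test_invariant_to_other_measures(self, small_cohort):
        from neuroforage import simulate_cohort
        from neuroforage.maze import code_trial, summaries_to_frame

        summ = summaries_to_frame(
            [code_trial(t) for tl in simulate_cohort(small_cohort)
             for t in tl.trials])
        base = classify_cohort(daily_measure_table(summ))
        summ2 = summ.copy()
        summ2["saps_per_entry"] *= 100  # any other measure
        summ2["groom"] += 42
        again = classify_cohort(daily_measure_table(summ2))
        assert [(c.rat_id, c.affected) for c in base] == \
               [(c.rat_id, c.affected) for c in again]


class TestCounts:
    def test_all_zero_when_no_rat_exceeds(self):
        ref = flat_reference(1e9)
        calls = [classify_affected({d: 1.0 for d in range(1, 19)}, ref,
                                   rat_id=f"r{i}", group="cci_vehicle")
                 for i in range(5)]
        counts = cohort_phenotype_counts(calls)
        assert (counts[["week_1", "week_2", "week_3", "affected"]] == 0).all().all()

    def test_strong_effects_counted_exactly(self):
        ref = flat_reference(10.0)
        calls = []
        for i in range(37):
            v = 20.0 if i < 8 else 1.0  # 8 rats always above threshold
            calls.append(classify_affected({d: v for d in range(1, 19)}, ref,
                                           rat_id=f"r{i}", group="cci_vehicle"))
        counts = cohort_phenotype_counts(calls).set_index("group")
        assert counts.loc["cci_vehicle", "week_1"] == 8
        assert counts.loc["cci_vehicle", "affected"] == 8


class TestBehaviouralGroups:
    def make_calls(self, states):
        ref = flat_reference(10.0)
        calls = []
        for i, state in enumerate(states):
            v = 20.0 if state else 1.0
            calls.append(classify_affected({d: v for d in range(1, 19)}, ref,
                                           rat_id=f"cv{i}", group="cci_vehicle"))
        return calls

    def test_vehicle_cci_split_by_call(self):
        calls = self.make_calls([True, False, False])
        table = tidy([(f"cv{i}", "cci_vehicle", 1, "m", 1.0) for i in range(3)]
                     + [("s0", "sham_vehicle", 1, "m", 1.0)])
        out = assign_behavioural_groups(table, calls)
        labels = dict(zip(out["rat_id"], out["group"]))
        assert labels == {"cv0": "affected", "cv1": "unaffected",
                          "cv2": "unaffected", "s0": "sham_vehicle"}

    def test_indeterminate_rats_dropped_with_warning(self):
        ref = flat_reference(10.0)
        calls = [classify_affected({1: 11.0}, ref, rat_id="cv0",
                                   group="cci_vehicle")]
        table = tidy([("cv0", "cci_vehicle", 1, "m", 1.0),
                      ("s0", "sham_vehicle", 1, "m", 1.0)])
        with pytest.warns(UserWarning, match="indeterminate"):
            out = assign_behavioural_groups(table, calls)
        assert list(out["rat_id"]) == ["s0"]


class TestExpectedNullCount:
    @pytest.mark.parametrize("k, n_ref, n_tgt, expected", [
        (8, 37, 21, 5),     # 4.54 rounds up
        (0, 37, 21, 0),
        (37, 37, 21, 21),   # identity proportion
        (1, 4, 2, 1),       # 0.5 rounds half away from zero
    ])
    def test_values(self, k, n_ref, n_tgt, expected):
        assert expected_null_count(k, n_ref, n_tgt) == expected

    def test_identity_property(self):
        for k in range(0, 38):
            assert expected_null_count(k, 37, 37) == k

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            expected_null_count(1, 0, 5)


class TestBinWeekly:
    def test_identical_days(self):
        t = tidy([("r1", "g", d, "m", 3.0) for d in range(1, 8)])
        b = bin_weekly(t)
        assert b[b["bin"] == "days_1_7"]["value"].iloc[0] == 3.0

    def test_running_values(self):
        t = tidy([("r1", "g", d, "m", float(d)) for d in range(1, 8)])
        b = bin_weekly(t)
        assert b[b["bin"] == "days_1_7"]["value"].iloc[0] == 4.0

    def test_missing_day_averages_rest(self):
        t = tidy([("r1", "g", d, "m", float(d)) for d in range(1, 8) if d != 7])
        row = bin_weekly(t).set_index("bin").loc["days_1_7"]
        assert row["value"] == pytest.approx(3.5)
        assert row["n_days"] == 6

    def test_empty_bin_flagged(self):
        t = tidy([("r1", "g", 1, "m", 1.0)])
        row = bin_weekly(t).set_index("bin").loc["days_8_14"]
        assert np.isnan(row["value"]) and row["n_days"] == 0


def test_null_false_affected_rate_below_half_percent():
    """3-SD daily thresholds compounded over two windows are highly specific."""
    rate = null_false_affected_rate(n_rats=10_000, n_sham=9, seed=0)
    assert rate < 0.005
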