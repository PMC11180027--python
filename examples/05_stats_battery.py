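"""The statistical battery on binned behavioural data.

Daily normalised measures are cleaned with the 3×IQR rule, binned into
seven-day periods, and tested with a mixed ANOVA (group × bin) with
Holm-corrected pairwise post hocs. The a priori power computation sizes a
one-way design from an expected effect size.
"""

from neuroforage import CohortConfig, simulate_cohort
from neuroforage.maze import code_trial, summaries_to_frame
from neuroforage.phenotype import (assign_behavioural_groups, bin_weekly,
                                   classify_cohort, daily_measure_table,
                                   remove_outliers)
from neuroforage.stats import anova_power_n, mixed_anova, posthoc_holm

timelines = simulate_cohort(CohortConfig(seed=8))
summaries = summaries_to_frame(
    [code_trial(t) for tl in timelines for t in tl.trials])

tidy = daily_measure_table(summaries, measures=["tica_per_entry"])
# split the vehicle nerve-injured group by phenotype: the five behavioural
# groups are the units of all group-level comparisons
tidy = assign_behavioural_groups(tidy, classify_cohort(
    daily_measure_table(summaries)))
cleaned, removals = remove_outliers(tidy)
print(f"outlier rule removed {len(removals)} daily values")

binned = bin_weekly(cleaned).dropna(subset=["value"])
res = mixed_anova(binned, dv="value", between="group", within="bin",
                  subject="rat_id", gg_correct="auto")
print("\nMixed ANOVA on normalised central-atrium time:")
for r in res:
    print(f"  {r.effect:>12}: F({r.df1:.4g}, {r.df2:.4g}) = {r.F:.2f}, "
          f"p = {r.p:.2g} [{r.correction}]")

week1 = binned[binned["bin"] == "days_1_7"]
ph = posthoc_holm(week1, dv="value", group="group")
sig = ph[ph["p_adj"] < 0.05]
print(f"\nHolm-corrected post hocs, days 1-7: "
      f"{len(sig)}/{len(ph)} pairs significant")
print(sig.round(4).to_string(index=False))

n = anova_power_n(f=0.8, k=5, alpha=0.05, power=0.8)
print(f"\nA priori power: f=0.8, 5 groups, alpha=.05, power=.8 "
      f"-> n = {n} per group")
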