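"""Simulate a small cohort and code its radial-arm-maze trials.

Each simulated trial is a time-ordered event sequence (atrium dwells, arm
entries, nose pokes, stretch-attend postures, grooming...). Coding labels
every arm entry (PE / PO / WME / RME / HME) from the visit history against
the baited set {1, 2, 4, 7} and aggregates all endpoints per trial, both
raw and normalised per arm entry.
"""

from neuroforage import CohortConfig, simulate_cohort
from neuroforage.maze import code_trial, summaries_to_frame

cohort = CohortConfig(group_sizes={"sham_vehicle": 4, "cci_vehicle": 8},
                      n_days_post=5, seed=11)
timelines = simulate_cohort(cohort)
summaries = summaries_to_frame(
    [code_trial(t) for tl in timelines for t in tl.trials])

first = summaries.iloc[0]
print(f"rat {first['rat_id']}, day {int(first['day'])}:")
print(f"  entries={int(first['total_entries'])}  PE={int(first['pe'])} "
      f"PO={int(first['po'])}  WME={int(first['wme_total'])} "
      f"RME={int(first['rme_total'])} (incl. hybrids)")
print(f"  TICA={first['tica']:.1f}s  -> {first['tica_per_entry']:.2f} s/entry "
      "(the classification measure)")

by_group = summaries.groupby("group")[["tica_per_entry", "saps_per_entry",
                                       "rme_total"]].mean().round(2)
print("\nGroup means over all rat-days:")
print(by_group.to_string())
print("\nNerve-injured rats that carry the latent affected phenotype dwell "
      "longer in the central atrium per entry than shams.")
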