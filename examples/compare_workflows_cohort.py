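"""Compare the three LLOQ determinations across a multi-site cohort.

Generates a 65-run synthetic cohort (six sites, four protocol arms, three
rounds, diverse noise and NTC behavior) and tabulates the LLOQ from the
baseline-noise tree and both logistic options for every run.
"""

from qlloq import compare_methods, summarize_comparison
from qlloq.synthetic import multisite_cohort

runs = multisite_cohort(seed=1)
table = compare_methods(runs)
print(table[["run_id", "lowest_calibrator", "baseline_noise",
             "logistic_re", "logistic_se"]].head(8).to_string(index=False))
print("  ...")

s = summarize_comparison(table)
print(f"\nacross {s['n_runs']} runs:")
print(f"  baseline-noise LLOQ above the lowest calibrator: "
      f"{s['baseline_pct_above_lowest_calibrator']:.0f}%")
print(f"  relative-error LLOQ at the lowest calibrator:    "
      f"{s['logistic_re_pct_at_lowest_calibrator']:.0f}%")
print(f"  standard-error LLOQ at the lowest calibrator:    "
      f"{s['logistic_se_pct_at_lowest_calibrator']:.0f}%")
print(f"  RE and SE options agree on {s['re_se_agreement_runs']} runs; "
      f"SE >= RE in {s['se_ge_re_among_discordant']} of "
      f"{s['n_discordant']} discordant runs")
print(f"  NTC background present (node 1): {s['baseline_node1_pct']:.0f}% of runs")
print("\nThe baseline-noise tree is the most conservative workflow; the "
      "relative-error option is the least.")
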