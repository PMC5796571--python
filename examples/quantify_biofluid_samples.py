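"""Quantify unknowns as copies/µL and flag values below the LLOQ.

A synthetic biofluid study: 14 calibration runs with 104 unknowns spread
across them, quantified per run from that run's own curve and filtered by
each run's own LLOQ. The volume factor is anchored to a documented
equivalence (300 amol/L of calibrator = 36.7 copies/µL of biofluid).
"""

from qlloq import quantify_run, volume_factor_from_equivalence
from qlloq.synthetic import biofluid_study

vf = volume_factor_from_equivalence(300.0, 36.7)
runs = biofluid_study(seed=4)

for method in ("baseline_noise", "logistic_se"):
    above = below = no_estimate = 0
    for run in runs:
        for q in quantify_run(run, method, volume_factor=vf):
            if q.copies_per_ul is None:
                no_estimate += 1
            if q.below_lloq:
                below += 1
            else:
                above += 1
    total = above + below
    print(f"{method}: {above}/{total} measurements at/above the LLOQ "
          f"({below} filtered, {no_estimate} with no estimate at all)")

one = quantify_run(runs[0], "logistic_se", volume_factor=vf)[0]
print(f"\nexample: sample {one.sample_id} in run {one.run_id}: "
      f"{one.copies_per_ul:,.1f} copies/µL "
      f"(95% CI {one.ci95_low:,.1f} - {one.ci95_high:,.1f}), "
      f"LLOQ {one.lloq_copies_per_ul:,.1f}, below_lloq={one.below_lloq}")
print("\nSub-LLOQ estimates are retained with their flag: the LLOQ filters "
      "reporting, it does not delete data.")
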