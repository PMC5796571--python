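"""Determine an LLOQ from the logistic fit, both error options.

For every calibrator the run's mean Cq is inverse-predicted and an error
metric computed: percent relative error against the known concentration
(threshold 20%), or the delta-method SE of the inverse prediction
(threshold 0.25 log10 units). The LLOQ is the smallest concentration in
any consecutive pair of calibrators that both pass.
"""

from qlloq import fit_3pl, lloq_relative_error, lloq_standard_error
from qlloq.synthetic import SimScenario, generate_run

run = generate_run(SimScenario(cq_noise_sd=0.2, seed=7))
fit = fit_3pl(run)

for res in (lloq_relative_error(fit, run), lloq_standard_error(fit, run)):
    print(f"\n{res.method} (threshold {res.threshold_used:g}):")
    for d in res.per_calibrator:
        metric = "   --" if d.metric is None else f"{d.metric:6.2f}"
        flag = "pass" if d.passed else "FAIL"
        print(f"  {d.concentration:>12,.1f} amol/L  metric {metric}  {flag}")
    lloq = "missing" if res.missing else f"{res.lloq_amol_per_l:,.1f} amol/L"
    print(f"  -> LLOQ = {lloq}")

print("\nBelow the LLOQ, inverse predictions are too inaccurate (RE option) "
      "or too uncertain (SE option) to report quantitatively.")
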