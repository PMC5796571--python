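"""Per-run sample quantitation with LLOQ flagging, and multi-run
method comparison.

A run's unknowns are inverse-predicted from that run's own calibration
fit; the LLOQ is likewise computed per run ("per-run basis"), so every
flag is self-contained. Sub-LLOQ estimates are reported alongside the
flag rather than blanked out — downstream users can always censor, but
cannot recover a discarded estimate or its error bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .calibration import Fit3PL, fit_3pl, inverse_predict
from .lloq_baseline import lloq_baseline_noise
from .lloq_logistic import lloq_relative_error, lloq_standard_error
from .types import CalibrationRun, CqValue, LloqResult

__all__ = [
    "SampleQuantitation",
    "quantify_run",
    "compare_methods",
    "amol_per_l_to_copies_per_ul",
    "copies_per_ul_to_amol_per_l",
    "volume_factor_from_equivalence",
    "compute_lloq",
    "METHODS",
]

AVOGADRO = 6.02214076e23
# copies/µL of reaction per amol/L: 1e-18 mol/L * N_A, per 1e6 µL/L
_COPIES_PER_UL_PER_AMOL_PER_L = 1e-18 * AVOGADRO / 1e6

METHODS = ("baseline_noise", "logistic_re", "logistic_se")


def amol_per_l_to_copies_per_ul(conc_amol_per_l: float, volume_factor: float = 1.0) -> float:
    """Convert a calibrator-scale concentration to copies per µL of
    biofluid equivalent. volume_factor captures the dataset's dilution
    chain (µL of biofluid represented per µL of reaction); 1.0 means the
    reaction concentration itself."""
    return conc_amol_per_l * _COPIES_PER_UL_PER_AMOL_PER_L * volume_factor


def copies_per_ul_to_amol_per_l(copies_per_ul: float, volume_factor: float = 1.0) -> float:
    return copies_per_ul / (_COPIES_PER_UL_PER_AMOL_PER_L * volume_factor)


def volume_factor_from_equivalence(conc_amol_per_l: float, copies_per_ul: float) -> float:
    """Back out the volume factor from one stated equivalence, e.g. a
    dataset documented as "0.3 fmol/L corresponds to 36.7 copies/µL"."""
    return copies_per_ul / (conc_amol_per_l * _COPIES_PER_UL_PER_AMOL_PER_L)


@dataclass
class SampleQuantitation:
    """One unknown's predicted level with its CI and LLOQ flag."""

    sample_id: str
    run_id: str
    copies_per_ul: Optional[float]
    ci95_low: Optional[float]
    ci95_high: Optional[float]
    lloq_copies_per_ul: Optional[float]
    below_lloq: bool
    lloq_method: str
    n_replicates: int = 1
    notes: str = ""


def compute_lloq(run: CalibrationRun, method: str, fit: Optional[Fit3PL] = None, **kw) -> LloqResult:
    """Dispatch one LLOQ determination; fits the curve if needed."""
    if method == "baseline_noise":
        return lloq_baseline_noise(
            run,
            undetermined_policy=kw.get("undetermined_policy", "all"),
            tie_break=kw.get("tie_break", "high"),
        )
    if fit is None:
        fit = fit_3pl(run)
    if method == "logistic_re":
        return lloq_relative_error(fit, run, kw.get("re_threshold", 20.0))
    if method == "logistic_se":
        return lloq_standard_error(
            fit, run, kw.get("se_threshold", 0.25), scale=kw.get("se_scale", "log10")
        )
    raise ValueError(f"unknown LLOQ method {method!r}; choose from {METHODS}")


def _group_replicates(unknowns: Sequence[tuple[str, CqValue]]) -> dict[str, list[CqValue]]:
    grouped: dict[str, list[CqValue]] = {}
    for sample_id, cq in unknowns:
        grouped.setdefault(sample_id, []).append(cq)
    return grouped


def quantify_run(
    run: CalibrationRun,
    method: str = "logistic_se",
    volume_factor: float = 1.0,
    **lloq_kw,
) -> list[SampleQuantitation]:
    """Quantify every unknown in a run and flag sub-LLOQ values.

    Replicate wells of the same sample_id are averaged before inversion
    and the replicate count shrinks the new-observation variance term.
    An indeterminate LLOQ leaves estimates intact but flags them
    "lloq_indeterminate"; an unknown with a censored Cq gets no estimate
    and counts as below the LLOQ whenever one exists.
    """
    if not run.unknowns:
        raise ValueError(f"run {run.run_id} has no unknowns to quantify")
    fit = fit_3pl(run)
    lloq_res = compute_lloq(run, method, fit=fit, **lloq_kw)
    lloq_copies = (
        None
        if lloq_res.missing
        else amol_per_l_to_copies_per_ul(lloq_res.lloq_amol_per_l, volume_factor)
    )

    out: list[SampleQuantitation] = []
    for sample_id, cqs in _group_replicates(run.unknowns).items():
        non_cens = [c for c in cqs if not c.censored]
        if not non_cens or not fit.converged:
            note = "censored Cq" if not non_cens else "calibration fit did not converge"
            out.append(
                SampleQuantitation(
                    sample_id=sample_id,
                    run_id=run.run_id,
                    copies_per_ul=None,
                    ci95_low=None,
                    ci95_high=None,
                    lloq_copies_per_ul=lloq_copies,
                    below_lloq=lloq_copies is not None,
                    lloq_method=method if lloq_copies is not None else "lloq_indeterminate",
                    n_replicates=len(cqs),
                    notes=note,
                )
            )
            continue
        mean = sum(c.value for c in non_cens) / len(non_cens)
        pred = inverse_predict(fit, mean, n_replicates=len(non_cens))
        if pred.ok:
            est = amol_per_l_to_copies_per_ul(pred.conc_hat, volume_factor)
            lo = amol_per_l_to_copies_per_ul(pred.ci95_low, volume_factor)
            hi = amol_per_l_to_copies_per_ul(pred.ci95_high, volume_factor)
        else:
            est = lo = hi = None
        below = (
            lloq_copies is not None and (est is None or est < lloq_copies)
        )
        out.append(
            SampleQuantitation(
                sample_id=sample_id,
                run_id=run.run_id,
                copies_per_ul=est,
                ci95_low=lo,
                ci95_high=hi,
                lloq_copies_per_ul=lloq_copies,
                below_lloq=below,
                lloq_method=method if lloq_copies is not None else "lloq_indeterminate",
                n_replicates=len(cqs),
                notes="" if pred.ok else "Cq outside invertible range",
            )
        )
    return out


def compare_methods(runs: Sequence[CalibrationRun], **lloq_kw) -> pd.DataFrame:
    """LLOQs under all three methods for each run, one row per run.

    Columns: run_id, site, multiplicity, lowest_calibrator, one LLOQ column
    per method, the baseline decision node, and convenience booleans.
    Summaries derive from this frame via summarize_comparison.
    """
    rows = []
    for run in runs:
        try:
            fit = fit_3pl(run)
        except Exception:
            fit = None
        row: dict = {
            "run_id": run.run_id,
            "site": run.site,
            "multiplicity": run.multiplicity,
            "lowest_calibrator": run.lowest_concentration,
        }
        for method in METHODS:
            try:
                res = compute_lloq(run, method, fit=fit, **lloq_kw)
            except Exception as exc:  # e.g. missing NTC
                row[method] = math.nan
                row[f"{method}_path"] = f"error: {exc}"
                continue
            row[method] = math.nan if res.missing else res.lloq_amol_per_l
            row[f"{method}_path"] = res.decision_path
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_comparison(table: pd.DataFrame) -> dict:
    """Cohort-level summary of a compare_methods table.

    Reports, per method, the percent of runs whose LLOQ equals the lowest
    calibrator; the percent of baseline LLOQs strictly above it; logistic
    RE-vs-SE agreement; how often SE >= RE among discordant runs; and the
    baseline node-1 routing fraction.
    """
    n = len(table)
    out: dict = {"n_runs": n}
    for method in METHODS:
        at_lowest = (table[method] == table["lowest_calibrator"]).sum()
        out[f"{method}_pct_at_lowest_calibrator"] = 100.0 * at_lowest / n
    above = (table["baseline_noise"] > table["lowest_calibrator"]).sum()
    out["baseline_pct_above_lowest_calibrator"] = 100.0 * above / n

    re_, se_ = table["logistic_re"], table["logistic_se"]
    both_missing = re_.isna() & se_.isna()
    agree = (re_ == se_) | both_missing
    out["re_se_agreement_runs"] = int(agree.sum())
    discordant = table[~agree].dropna(subset=["logistic_re", "logistic_se"])
    out["n_discordant"] = int((~agree).sum())
    out["se_ge_re_among_discordant"] = int((discordant["logistic_se"] >= discordant["logistic_re"]).sum())

    node1 = (table["baseline_noise_path"] == "node1").sum()
    out["baseline_node1_pct"] = 100.0 * node1 / n
    return out
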