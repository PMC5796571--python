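"""LLOQ determination from the logistic calibration fit.

Two interchangeable error metrics are evaluated at every calibrator's mean
Cq, scanning the series in ascending concentration:

* relative-error option: the percent relative error of the inverse
  prediction against the known concentration, threshold 20%;
* standard-error option: the delta-method standard error of the inverse
  prediction on the log10-concentration scale, threshold 0.25.

Either way, the rule is the same: find every consecutive pair of
calibrators whose metrics both fall below the threshold, and report the
smallest concentration occurring in any such pair; if no pair qualifies the
LLOQ is missing. A calibrator whose replicates are all censored has no mean
Cq and automatically fails.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

from .calibration import Fit3PL, inverse_predict, relative_error_percent
from .types import CalibrationRun, CalibratorDiagnostic, LloqResult

__all__ = ["lloq_relative_error", "lloq_standard_error", "consecutive_pair_lloq"]


def consecutive_pair_lloq(
    concentrations: Sequence[float],
    metrics: Sequence[Optional[float]],
    threshold: float,
) -> Optional[float]:
    """Apply the two-consecutive-values rule to a metric profile.

    concentrations must be ascending; a metric of None always fails.
    "Below the threshold" is strict: a metric exactly at the threshold
    fails. Returns the smallest concentration belonging to any passing
    pair, or None.
    """
    if len(concentrations) != len(metrics):
        raise ValueError("concentrations and metrics must align")
    passed = [m is not None and m < threshold for m in metrics]
    for i in range(len(passed) - 1):
        if passed[i] and passed[i + 1]:
            # ascending order: the first passing pair holds the smallest
            # concentration among all passing pairs
            return concentrations[i]
    return None


def _lloq_by_metric(
    fit: Fit3PL,
    run: CalibrationRun,
    threshold: float,
    method: str,
    metric_fn: Callable[[float, float], Optional[float]],
) -> LloqResult:
    if not fit.converged:
        return LloqResult(
            lloq_amol_per_l=None,
            method=method,
            decision_path="indeterminate — poor fit",
            threshold_used=threshold,
            run_id=run.run_id,
            notes="logistic model did not converge",
        )
    diagnostics: list[CalibratorDiagnostic] = []
    concs: list[float] = []
    metrics: list[Optional[float]] = []
    for point in run.calibrators:
        m = None if point.mean_cq is None else metric_fn(point.concentration, point.mean_cq)
        concs.append(point.concentration)
        metrics.append(m)
        diagnostics.append(
            CalibratorDiagnostic(point.concentration, m, m is not None and m < threshold)
        )
    lloq = consecutive_pair_lloq(concs, metrics, threshold)
    return LloqResult(
        lloq_amol_per_l=lloq,
        method=method,
        decision_path="consecutive-pair scan" if lloq is not None else "no qualifying pair",
        per_calibrator=diagnostics,
        threshold_used=threshold,
        run_id=run.run_id,
    )


def lloq_relative_error(
    fit: Fit3PL, run: CalibrationRun, threshold_pct: float = 20.0
) -> LloqResult:
    """LLOQ via the percent-relative-error metric (default threshold 20%)."""

    def metric(conc: float, mean_cq: float) -> Optional[float]:
        pred = inverse_predict(fit, mean_cq)
        if not pred.ok:
            return None
        return relative_error_percent(conc, pred.conc_hat)

    return _lloq_by_metric(fit, run, threshold_pct, "logistic_re", metric)


def lloq_standard_error(
    fit: Fit3PL, run: CalibrationRun, threshold_se: float = 0.25, scale: str = "log10"
) -> LloqResult:
    """LLOQ via the inverse-prediction standard error (default threshold 0.25).

    The metric lives on the log10-concentration scale by default — the scale
    the model and its confidence intervals are built on; 0.25 log10 units is
    about a 1.8-fold uncertainty. scale="ln" converts to natural-log units.
    """
    if scale not in ("log10", "ln"):
        raise ValueError(f"scale must be 'log10' or 'ln', got {scale!r}")
    factor = 1.0 if scale == "log10" else 2.302585092994046

    def metric(conc: float, mean_cq: float) -> Optional[float]:
        pred = inverse_predict(fit, mean_cq)
        if not pred.ok:
            return None
        return pred.se_log10 * factor

    return _lloq_by_metric(fit, run, threshold_se, "logistic_se", metric)
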