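"""Three-parameter logistic (3PL) calibration and inverse prediction.

The model relates the quantification cycle to template input as

    Cq(z) = c / (1 + exp(g * (z - b))),    z = log10(concentration, amol/L)

with c the upper Cq plateau reached at vanishing input, b the midpoint on
the log10-concentration axis, and g > 0 a rate, so the fitted curve is
monotone non-increasing in concentration. The lower asymptote is pinned at
zero — it is never approached inside a calibration series, which bottoms
out around the top-calibrator Cq.

Inverse prediction solves the fitted curve for concentration given an
observed Cq,

    z(y) = b + (1/g) * ln(c/y - 1),

and propagates parameter and replicate uncertainty into a standard error on
the log10 scale by a first-order Taylor (delta-method) expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, InvalidFitError
from .types import CalibrationRun, CqValue

__all__ = [
    "Fit3PL",
    "InversePrediction",
    "fit_3pl",
    "predict_cq",
    "inverse_predict",
    "relative_error_percent",
]

Z95 = 1.96  # two-sided 95% normal quantile

# Curvature of the exponent is clipped to keep exp() finite; |u| = 500 maps
# to a Cq indistinguishable from the asymptote at double precision.
_EXP_CLIP = 500.0


def _logistic3(z: np.ndarray, c: float, g: float, b: float) -> np.ndarray:
    u = np.clip(g * (np.asarray(z, dtype=float) - b), -_EXP_CLIP, _EXP_CLIP)
    return c / (1.0 + np.exp(u))


@dataclass
class Fit3PL:
    """A fitted 3PL calibration curve with its uncertainty.

    param_covariance is the 3x3 covariance of (c, g, b) estimated as
    sigma^2 (J^T J)^-1; residual_variance is SSE/(n-3) in Cq^2 units.
    """

    asymptote_c: float
    rate_g: float
    midpoint_b: float
    param_covariance: np.ndarray
    residual_variance: float
    n_points_used: int
    converged: bool
    rmse: float

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.asymptote_c, self.rate_g, self.midpoint_b)


@dataclass
class InversePrediction:
    """Concentration read off the fitted curve for one observed Cq."""

    log10_conc_hat: Optional[float]
    se_log10: Optional[float]
    conc_hat: Optional[float]
    ci95_low: Optional[float]
    ci95_high: Optional[float]
    status: str  # "ok" | "out_of_range"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _replicate_points(run: CalibrationRun) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-level (log10 conc, Cq) pairs, censored replicates dropped."""
    zs, ys = [], []
    for point in run.calibrators:
        for cq in point.replicate_cqs:
            if not cq.censored:
                zs.append(point.log10_concentration)
                ys.append(cq.value)
    return np.asarray(zs), np.asarray(ys)


def _initial_guesses(z: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting values: plateau above the data ceiling, midpoint
    at the median z, rate converted from a straight-line slope through the
    middle half of the points."""
    c0 = 1.05 * float(np.max(y))
    b0 = float(np.median(z))
    lo, hi = np.percentile(z, [25, 75])
    mid = (z >= lo) & (z <= hi)
    if mid.sum() >= 2 and np.ptp(z[mid]) > 0:
        slope = float(np.polyfit(z[mid], y[mid], 1)[0])
    else:
        slope = float(np.polyfit(z, y, 1)[0]) if np.ptp(z) > 0 else -1.0
    # at the midpoint the 3PL slope is -c*g/4
    g0 = max(4.0 * (-slope) / c0, 1e-3)
    return c0, g0, b0


def fit_3pl(run: CalibrationRun) -> Fit3PL:
    """Fit the 3PL curve to a run's replicate-level calibrator data.

    Nonlinear least squares with a deterministic multi-start: the analytic
    initial guess first, then a small grid of perturbations of (c0, g0) if
    the optimizer fails to converge. Raises InsufficientDataError with
    fewer than four usable calibrator points; optimizer failure after all
    starts yields a Fit3PL with converged=False (downstream LLOQ logic
    treats that as indeterminate).
    """
    usable = run.n_usable_calibrators()
    if usable < 4:
        raise InsufficientDataError(
            f"run {run.run_id}: {usable} usable calibrator points; "
            "3PL fitting needs at least 4"
        )
    z, y = _replicate_points(run)
    n = len(y)
    c0, g0, b0 = _initial_guesses(z, y)
    max_y = float(np.max(y))
    lower = (max_y - 0.5, 1e-8, -np.inf)
    upper = (np.inf, np.inf, np.inf)

    starts = [(c0, g0, b0)]
    for fc in (1.0, 0.9, 1.2):
        for fg in (1.0, 0.5, 2.0):
            cand = (max(fc * c0, max_y - 0.4), fg * g0, b0)
            if cand not in starts:
                starts.append(cand)

    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                _logistic3, z, y, p0=p0, bounds=(lower, upper),
                maxfev=20000, method="trf",
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((_logistic3(z, *popt) - y) ** 2))
        best = (popt, pcov, sse)
        break  # fallback starts are only for failed convergence

    if best is None:
        nan3 = np.full((3, 3), np.nan)
        return Fit3PL(np.nan, np.nan, np.nan, nan3, np.nan, n, False, np.nan)

    popt, pcov, sse = best
    dof = max(n - 3, 1)
    sigma2 = sse / dof
    rmse = math.sqrt(sse / n)
    return Fit3PL(
        asymptote_c=float(popt[0]),
        rate_g=float(popt[1]),
        midpoint_b=float(popt[2]),
        param_covariance=np.asarray(pcov, dtype=float),
        residual_variance=sigma2,
        n_points_used=n,
        converged=True,
        rmse=rmse,
    )


def predict_cq(fit: Fit3PL, log10_conc: float) -> float:
    """Forward-evaluate the fitted curve at z = log10(concentration)."""
    if not fit.converged:
        raise InvalidFitError("cannot predict from a non-converged fit")
    return float(_logistic3(np.asarray([log10_conc]), *fit.params)[0])


def inverse_predict(
    fit: Fit3PL,
    observed_cq: CqValue | float,
    n_replicates: int = 1,
    include_new_observation: bool = True,
    interior_eps_frac: float = 0.01,
) -> InversePrediction:
    """Invert the fitted curve at one observed Cq.

    The variance of the log10-concentration estimate combines parameter
    uncertainty (gradient of the inverse map against the parameter
    covariance) with the replicate-noise contribution of the new
    observation, (dz/dy)^2 * sigma^2 / n_replicates. Setting
    include_new_observation=False drops the second term, giving a
    confidence interval for the curve inversion itself rather than a
    prediction interval for a new sample.

    Observations that are censored, or that fall within interior_eps_frac*c
    of either asymptote, are out of range: the logistic flattens there and
    the inversion is unstable or undefined.
    """
    if not fit.converged:
        raise InvalidFitError("cannot inverse-predict from a non-converged fit")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    if isinstance(observed_cq, CqValue):
        if observed_cq.censored:
            return InversePrediction(None, None, None, None, None, "out_of_range")
        y = observed_cq.value
    else:
        y = float(observed_cq)

    c, g, b = fit.params
    eps = interior_eps_frac * c
    if not (eps < y < c - eps):
        return InversePrediction(None, None, None, None, None, "out_of_range")

    ratio = c / y - 1.0
    z_hat = b + math.log(ratio) / g

    # delta method: gradient of z(c, g, b; y)
    dz_dc = 1.0 / (g * (c - y))
    dz_dg = -math.log(ratio) / g**2
    dz_db = 1.0
    grad = np.array([dz_dc, dz_dg, dz_db])
    var = float(grad @ fit.param_covariance @ grad)
    if include_new_observation:
        dz_dy = -c / (g * y * (c - y))
        var += dz_dy**2 * fit.residual_variance / n_replicates
    se = math.sqrt(max(var, 0.0))

    conc = 10.0**z_hat
    return InversePrediction(
        log10_conc_hat=z_hat,
        se_log10=se,
        conc_hat=conc,
        ci95_low=10.0 ** (z_hat - Z95 * se),
        ci95_high=10.0 ** (z_hat + Z95 * se),
        status="ok",
    )


def relative_error_percent(known_conc: float, predicted_conc: float) -> float:
    """Percent relative error of an inverse prediction against the known
    calibrator concentration: 100 * |known - predicted| / known."""
    if known_conc <= 0:
        raise ValueError(f"known concentration must be > 0, got {known_conc}")
    return 100.0 * abs(known_conc - predicted_conc) / known_conc
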