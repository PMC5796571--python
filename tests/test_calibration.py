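"""3PL fitting, forward/inverse prediction, and the delta-method SE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qlloq.calibration import (
    Z95,
    fit_3pl,
    inverse_predict,
    predict_cq,
    relative_error_percent,
)
from qlloq.errors import InsufficientDataError, InvalidFitError
from qlloq.synthetic import DEFAULT_PARAMS, SimScenario, generate_run
from qlloq.types import CalibrationRun, CalibratorPoint, CqValue, NtcSet


class TestFit:
    def test_zero_noise_recovers_true_parameters(self, clean_fit):
        for est, true in zip(clean_fit.params, DEFAULT_PARAMS):
            assert abs(est - true) < 1e-6
        assert clean_fit.converged
        assert clean_fit.rmse < 1e-6

    def test_covariance_symmetric_psd_diagonal(self, noisy_fit):
        cov = noisy_fit.param_covariance
        assert np.allclose(cov, cov.T)
        assert (np.diag(cov) >= 0).all()
        assert noisy_fit.residual_variance >= 0

    def test_plateau_sits_at_or_above_data_ceiling(self, noisy_run, noisy_fit):
        max_cq = max(
            cq.value
            for p in noisy_run.calibrators
            for cq in p.replicate_cqs
            if not cq.censored
        )
        assert noisy_fit.asymptote_c >= max_cq - 0.5

    def test_fitted_curve_monotone_non_increasing(self, noisy_fit):
        zs = np.linspace(0.0, 7.0, 200)
        ys = [predict_cq(noisy_fit, z) for z in zs]
        assert all(a >= b - 1e-12 for a, b in zip(ys, ys[1:]))

    def test_three_points_insufficient(self):
        run = generate_run(SimScenario(n_dilutions=4, cq_noise_sd=0.0))
        short = CalibrationRun(
            "short", run.calibrators[:3], run.ntc, dilution_factor=3.0
        )
        with pytest.raises(InsufficientDataError):
            fit_3pl(short)

    def test_censored_replicates_excluded_not_fatal(self):
        run = generate_run(
            SimScenario(cq_noise_sd=0.2, seed=3, censor_ceiling=36.0)
        )
        fit = fit_3pl(run)
        assert fit.converged
        total_reps = sum(len(p.replicate_cqs) for p in run.calibrators)
        assert fit.n_points_used < total_reps  # ceiling censored the low end

    def test_fit_invariant_to_replicate_ordering(self, noisy_run, noisy_fit):
        shuffled = CalibrationRun(
            "shuffled",
            [
                CalibratorPoint(p.concentration, tuple(reversed(p.replicate_cqs)))
                for p in noisy_run.calibrators
            ],
            noisy_run.ntc,
            dilution_factor=3.0,
        )
        refit = fit_3pl(shuffled)
        assert refit.params == pytest.approx(noisy_fit.params, abs=1e-9)

    def test_parameter_bias_small_over_many_seeds(self):
        """Median relative bias of each parameter < 5% at SD 0.2, 3x10 design."""
        rel = []
        for seed in range(200):
            fit = fit_3pl(
                generate_run(
                    SimScenario(cq_noise_sd=0.2, n_dilutions=10, seed=seed)
                )
            )
            rel.append(
                [
                    (est - true) / true
                    for est, true in zip(fit.params, DEFAULT_PARAMS)
                ]
            )
        med = np.median(np.abs(rel), axis=0)
        assert (med < 0.05).all()


class TestForwardPrediction:
    def test_midpoint_gives_half_asymptote(self, clean_fit):
        assert predict_cq(clean_fit, clean_fit.midpoint_b) == pytest.approx(
            clean_fit.asymptote_c / 2
        )

    def test_asymptotic_limits(self, clean_fit):
        assert predict_cq(clean_fit, 1e6) == pytest.approx(0.0, abs=1e-12)
        assert predict_cq(clean_fit, -1e6) == pytest.approx(
            clean_fit.asymptote_c, abs=1e-12
        )

    def test_requires_converged_fit(self, clean_fit):
        import dataclasses

        bad = dataclasses.replace(clean_fit, converged=False)
        with pytest.raises(InvalidFitError):
            predict_cq(bad, 3.0)
        with pytest.raises(InvalidFitError):
            inverse_predict(bad, 30.0)


class TestInversePrediction:
    @given(z=st.floats(min_value=1.5, max_value=6.0))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, noisy_fit, z):
        pred = inverse_predict(noisy_fit, predict_cq(noisy_fit, z))
        assert pred.ok
        assert abs(pred.log10_conc_hat - z) < 1e-9

    def test_noiseless_limit_exact_with_zero_se(self, clean_fit):
        y = predict_cq(clean_fit, 4.0)
        pred = inverse_predict(clean_fit, y)
        assert pred.conc_hat == pytest.approx(1e4, rel=1e-9)
        assert pred.se_log10 == pytest.approx(0.0, abs=1e-6)

    def test_censored_observation_out_of_range(self, noisy_fit):
        pred = inverse_predict(noisy_fit, CqValue.undetermined())
        assert pred.status == "out_of_range"
        assert pred.se_log10 is None and pred.conc_hat is None

    def test_observations_near_asymptotes_out_of_range(self, noisy_fit):
        c = noisy_fit.asymptote_c
        for y in (0.0, 0.005 * c, c - 0.005 * c, c, c + 1.0):
            assert inverse_predict(noisy_fit, y).status == "out_of_range"

    def test_ci_brackets_estimate_symmetrically_in_log(self, noisy_fit):
        pred = inverse_predict(noisy_fit, 30.0)
        assert pred.ci95_low <= pred.conc_hat <= pred.ci95_high
        assert math.log10(pred.conc_hat / pred.ci95_low) == pytest.approx(
            Z95 * pred.se_log10
        )

    def test_se_grows_toward_both_asymptotes(self, noisy_fit):
        """Uncertainty blows up where the curve flattens."""
        c = noisy_fit.asymptote_c
        ys = np.linspace(0.02 * c, 0.98 * c, 60)
        ses = [inverse_predict(noisy_fit, y).se_log10 for y in ys]
        k = int(np.argmin(ses))
        assert all(a >= b - 1e-12 for a, b in zip(ses[:k], ses[1 : k + 1]))
        assert all(b >= a - 1e-12 for a, b in zip(ses[k:], ses[k + 1 :]))

    def test_replicate_mean_shrinks_se(self, noisy_fit):
        one = inverse_predict(noisy_fit, 30.0, n_replicates=1)
        three = inverse_predict(noisy_fit, 30.0, n_replicates=3)
        assert three.se_log10 < one.se_log10

    def test_new_observation_term_optional(self, noisy_fit):
        with_term = inverse_predict(noisy_fit, 30.0)
        without = inverse_predict(noisy_fit, 30.0, include_new_observation=False)
        assert without.se_log10 < with_term.se_log10

    def test_delta_se_matches_parametric_bootstrap(self, noisy_fit, noisy_run):
        """Delta-method SE within 15% of a 2000-resample parametric bootstrap."""
        from qlloq.calibration import _logistic3

        y = predict_cq(noisy_fit, 4.0)
        delta_se = inverse_predict(noisy_fit, y).se_log10

        rng = np.random.default_rng(2024)
        sd = math.sqrt(noisy_fit.residual_variance)
        zs = np.array(
            [
                p.log10_concentration
                for p in noisy_run.calibrators
                for _ in p.replicate_cqs
            ]
        )
        mu = _logistic3(zs, *noisy_fit.params)
        zhats = []
        for _ in range(2000):
            ysim = mu + rng.normal(0.0, sd, size=len(mu))
            points: dict[float, list[float]] = {}
            for z, yv in zip(zs, ysim):
                points.setdefault(float(z), []).append(max(yv, 0.0))
            calibs = [
                CalibratorPoint(10.0**z, tuple(CqValue(v) for v in vs))
                for z, vs in sorted(points.items())
            ]
            brun = CalibrationRun("boot", calibs, NtcSet((CqValue.undetermined(),)))
            bfit = fit_3pl(brun)
            if not bfit.converged:
                continue
            pred = inverse_predict(bfit, y + rng.normal(0.0, sd))
            if pred.ok:
                zhats.append(pred.log10_conc_hat)
        assert len(zhats) > 1900
        boot_se = float(np.std(zhats, ddof=1))
        assert abs(delta_se - boot_se) / boot_se < 0.15

    def test_ci_coverage_near_nominal(self):
        """95% CI covers the true mid-range concentration 95% +/- 3pp."""
        conc_true = 1e4
        hits = 0
        n = 200
        for seed in range(n):
            run = generate_run(
                SimScenario(cq_noise_sd=0.2, seed=seed, unknowns=(conc_true,))
            )
            fit = fit_3pl(run)
            _, cq = run.unknowns[0]
            pred = inverse_predict(fit, cq)
            if pred.ok and pred.ci95_low <= conc_true <= pred.ci95_high:
                hits += 1
        assert 92.0 <= 100.0 * hits / n <= 98.0


class TestRelativeError:
    @pytest.mark.parametrize(
        "known, predicted, expected",
        [(100.0, 100.0, 0.0), (100.0, 80.0, 20.0), (10.0, 13.0, 30.0), (5.7, 5.7, 0.0)],
    )
    def test_known_values(self, known, predicted, expected):
        assert relative_error_percent(known, predicted) == pytest.approx(expected)

    def test_rejects_nonpositive_known(self):
        with pytest.raises(ValueError):
            relative_error_percent(0.0, 1.0)
        with pytest.raises(ValueError):
            relative_error_percent(-2.0, 1.0)
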