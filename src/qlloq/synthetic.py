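"""Synthetic calibration runs with the statistical structure of real
RT-qPCR dilution series.

What is emulated: a geometric (default 3-fold) serial dilution spanning
roughly four orders of magnitude, a sigmoidal Cq response that plateaus at
low template input, homoscedastic Gaussian replicate noise on Cq, an
instrument cycle ceiling (default 40) that censors any Cq beyond it as
"undetermined", NTC background signal drawn independently of the curve
(primer-dimer artifact model), and unknowns read through the same true
curve. Heteroscedastic plateau-inflated noise is available as an option
since real low-input scatter grows toward the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .types import CalibrationRun, CalibratorPoint, CqValue, NtcSet, geometric_series

__all__ = [
    "SimScenario",
    "generate_run",
    "node_fixture_suite",
    "true_cq",
    "DEFAULT_PARAMS",
    "multisite_cohort",
    "biofluid_study",
]

# (c, g, b): plateau ~38 Cq, midpoint at log10(conc) = 5.8, rate giving
# ~3.3 Cq per decade through the linear region — the shape of a typical
# miRNA standard curve from ~1 pmol/L down to the high-attomolar floor.
DEFAULT_PARAMS: tuple[float, float, float] = (38.0, 0.63, 5.8)


def true_cq(z: float, params: tuple[float, float, float]) -> float:
    """Noise-free Cq at z = log10(concentration amol/L) under the 3PL curve."""
    c, g, b = params
    u = min(max(g * (z - b), -500.0), 500.0)
    return c / (1.0 + np.exp(u))


@dataclass(frozen=True)
class SimScenario:
    """Full description of one simulated run; same seed, same bits out."""

    true_params: tuple[float, float, float] = DEFAULT_PARAMS
    n_dilutions: int = 11
    top_conc: float = 1e6  # amol/L == 1 pmol/L
    dilution_factor: float = 3.0
    replicates: int = 3
    cq_noise_sd: float = 0.2
    censor_ceiling: float = 40.0
    # NTC behavior: ("determined", mean, sd) or ("censored",)
    ntc_mode: tuple = ("censored",)
    ntc_replicates: int = 3
    unknowns: tuple[float, ...] = ()  # true concentrations, amol/L
    heteroscedastic: bool = False  # noise SD doubles linearly toward the plateau
    seed: int = 0
    run_id: str = "sim"
    site: str = "SIM"
    multiplicity: str = "singleplex"

    def with_(self, **kw) -> "SimScenario":
        return replace(self, **kw)


def _noise_sd(scn: SimScenario, z: float, z_lo: float, z_hi: float) -> float:
    if not scn.heteroscedastic or z_hi <= z_lo:
        return scn.cq_noise_sd
    frac = (z_hi - z) / (z_hi - z_lo)  # 0 at the top, 1 at the lowest dilution
    return scn.cq_noise_sd * (1.0 + frac)


def _censor(cq: float, ceiling: float) -> CqValue:
    return CqValue.undetermined() if cq > ceiling else CqValue(cq)


def generate_run(scenario: SimScenario) -> CalibrationRun:
    """Draw one calibration run from the scenario's noise model."""
    rng = np.random.default_rng(scenario.seed)
    concs = geometric_series(scenario.top_conc, scenario.dilution_factor, scenario.n_dilutions)
    z_lo, z_hi = np.log10(concs[0]), np.log10(concs[-1])

    calibrators = []
    for conc in concs:
        z = float(np.log10(conc))
        mu = true_cq(z, scenario.true_params)
        sd = _noise_sd(scenario, z, z_lo, z_hi)
        reps = [
            _censor(mu + rng.normal(0.0, sd) if sd > 0 else mu, scenario.censor_ceiling)
            for _ in range(scenario.replicates)
        ]
        calibrators.append(CalibratorPoint(conc, tuple(reps)))

    if scenario.ntc_mode[0] == "determined":
        _, ntc_mean, ntc_sd = scenario.ntc_mode
        ntc_reps = [
            _censor(
                ntc_mean + (rng.normal(0.0, ntc_sd) if ntc_sd > 0 else 0.0),
                scenario.censor_ceiling,
            )
            for _ in range(scenario.ntc_replicates)
        ]
    elif scenario.ntc_mode[0] == "censored":
        ntc_reps = [CqValue.undetermined() for _ in range(scenario.ntc_replicates)]
    else:
        raise ValueError(f"unknown ntc_mode {scenario.ntc_mode!r}")

    unknowns = []
    for i, conc in enumerate(scenario.unknowns):
        z = float(np.log10(conc))
        mu = true_cq(z, scenario.true_params)
        sd = _noise_sd(scenario, z, z_lo, z_hi)
        cq = _censor(mu + (rng.normal(0.0, sd) if sd > 0 else 0.0), scenario.censor_ceiling)
        unknowns.append((f"unk{i + 1}", cq))

    return CalibrationRun(
        run_id=scenario.run_id,
        site=scenario.site,
        multiplicity=scenario.multiplicity,
        dilution_factor=scenario.dilution_factor,
        calibrators=calibrators,
        ntc=NtcSet(tuple(ntc_reps)),
        unknowns=unknowns,
    )


def _fixed_run(
    run_id: str,
    mean_cqs: Sequence[Optional[float]],
    ntc_cq: Optional[float],
    top_conc: float = 1e6,
    factor: float = 3.0,
) -> CalibrationRun:
    """Deterministic run with exact mean Cqs (None = wholly censored point)."""
    concs = geometric_series(top_conc, factor, len(mean_cqs))
    calibrators = [
        CalibratorPoint(
            conc,
            (CqValue.undetermined(),) if cq is None else (CqValue(cq),),
        )
        for conc, cq in zip(concs, mean_cqs)
    ]
    ntc = NtcSet((CqValue.undetermined() if ntc_cq is None else CqValue(ntc_cq),))
    return CalibrationRun(
        run_id=run_id, calibrators=calibrators, ntc=ntc, dilution_factor=factor, site="FIX"
    )


def node_fixture_suite() -> list[CalibrationRun]:
    """Deterministic fixtures exercising every branch of the baseline tree
    plus its edge cases.

    Mean Cqs are listed in ascending concentration. The noiseless staircase
    drops ~1.58 Cq per 3-fold step through the linear region and flattens
    at the low end.
    """
    lin = [34.0, 33.0, 31.5, 29.9, 28.3, 26.7, 25.1, 23.5, 21.9, 20.3, 18.7]
    fixtures = [
        # node 1: NTC at 35 -> NTC+10 = 31.68; lowest point under it with a
        # monotone neighbor is the 3rd calibrator
        _fixed_run("fix-node1", lin, ntc_cq=35.0),
        # node 2: lowest dilution wholly censored, NTC censored
        _fixed_run("fix-node2", [None] + lin[1:], ntc_cq=None),
        # node 3: clean run, NTC censored, all points determined
        _fixed_run("fix-node3", lin, ntc_cq=None),
        # node 1 guard defeated at the first sub-NTC+10 candidate by a local
        # Cq inversion (point 3 reads lower than point 4)
        _fixed_run("fix-node1-inversion", [34.0, 33.0, 29.5, 29.9] + lin[4:], ntc_cq=35.0),
        # node 1 with a very clean (high-Cq) NTC: every non-top point passes
        _fixed_run("fix-node1-clean-ntc", lin, ntc_cq=39.0),
        # node 2 with the two lowest dilutions censored: floor at the higher
        _fixed_run("fix-node2-two-censored", [None, None] + lin[2:], ntc_cq=None),
        # flat profile: no point sits below NTC+10 and above its neighbor
        _fixed_run("fix-node1-allflat", [34.0] * 11, ntc_cq=35.0),
    ]
    return fixtures


def multisite_cohort(seed: int = 0) -> list[CalibrationRun]:
    """A 65-run multi-site calibration cohort.

    Emulates a study design of six sites (A-F) each running singleplex
    (with and without preamplification) and 4-plex arms, four of them also
    a Megaplex arm, each arm repeated over three rounds — 66 curves, one of
    which is dropped (a failed plate), leaving 65. Per-run curve shape,
    replicate noise, series length (10-12 dilutions of a 1 pmol/L stock)
    and NTC behavior vary across runs: NTC background signal is present in
    roughly 70% of runs, reflecting how often blank reactions pick up
    primer-artifact amplification in practice.
    """
    rng = np.random.default_rng(seed)
    sites = ["A", "B", "C", "D", "E", "F"]
    arms = [("singleplex-no-preamp", sites), ("singleplex-preamp", sites),
            ("4-plex", sites), ("Megaplex", sites[:4])]
    runs: list[CalibrationRun] = []
    idx = 0
    for arm_name, arm_sites in arms:
        for site in arm_sites:
            for rnd in (1, 2, 3):
                idx += 1
                c = rng.normal(38.0, 1.0)
                g = rng.normal(0.63, 0.06)
                b = rng.normal(5.8, 0.3)
                noise = rng.uniform(0.1, 0.4)
                n_dil = int(rng.integers(10, 13))
                if rng.random() < 0.7:
                    ntc_mode = ("determined", float(rng.uniform(33.0, 37.0)), 0.3)
                else:
                    ntc_mode = ("censored",)
                scn = SimScenario(
                    true_params=(c, g, b),
                    n_dilutions=n_dil,
                    top_conc=1e6,
                    dilution_factor=3.0,
                    replicates=3,
                    cq_noise_sd=noise,
                    censor_ceiling=40.0,
                    ntc_mode=ntc_mode,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    run_id=f"{site}-{arm_name}-r{rnd}",
                    site=site,
                    multiplicity=arm_name,
                )
                runs.append(generate_run(scn))
    # one failed plate: drop the last run to land on 65
    return runs[:-1]


def biofluid_study(seed: int = 0, n_unknowns: int = 104) -> list[CalibrationRun]:
    """A 14-run biofluid quantitation study with unknowns attached.

    Emulates five sites quantifying a cardiac-enriched miRNA in plasma and
    urine over repeated days: 14 calibration curves from a 2 pmol/L stock,
    four sites bottoming out near 0.3 fmol/L (9-point series) and one near
    0.03 fmol/L (11-point series), with the study's unknowns spread across
    runs. True unknown levels span control biofluids near or below the
    detection floor up to strongly elevated post-injury plasma, drawn
    log-uniformly over 10 amol/L - 0.1 pmol/L.
    """
    rng = np.random.default_rng(seed)
    runs: list[CalibrationRun] = []
    per_run = [n_unknowns // 14 + (1 if i < n_unknowns % 14 else 0) for i in range(14)]
    sites = ["P", "Q", "R", "S", "T"]
    k = 0
    for i in range(14):
        site = sites[i % 5]
        deep_series = site == "T"  # one site ran two extra dilutions
        n_dil = 11 if deep_series else 9
        c = rng.normal(38.0, 1.0)
        g = rng.normal(0.63, 0.06)
        b = rng.normal(5.8, 0.3)
        unknown_concs = 10.0 ** rng.uniform(1.0, 5.0, size=per_run[i])
        ntc_mode = (
            ("determined", float(rng.uniform(33.0, 37.0)), 0.3)
            if rng.random() < 0.7
            else ("censored",)
        )
        scn = SimScenario(
            true_params=(c, g, b),
            n_dilutions=n_dil,
            top_conc=2e6,
            dilution_factor=3.0,
            replicates=3,
            cq_noise_sd=float(rng.uniform(0.1, 0.4)),
            censor_ceiling=40.0,
            ntc_mode=ntc_mode,
            unknowns=tuple(float(x) for x in unknown_concs),
            seed=int(rng.integers(0, 2**31 - 1)),
            run_id=f"{site}-day{i // 5 + 1}-{i + 1}",
            site=site,
            multiplicity="singleplex-preamp",
        )
        runs.append(generate_run(scn))
        k += per_run[i]
    return runs
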