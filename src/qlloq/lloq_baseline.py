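"""LLOQ determination from baseline noise: a three-node decision tree.

The idea is the classic signal-to-noise-of-10 quantitation floor, with the
no-template control (NTC) standing in for the blank. Under perfect
per-cycle doubling, a 10-fold signal difference is log2(10) = 3.32 Cq.

Node 1 — the NTC produced a Cq (background artifact signal present):
    NTC+10 = mean NTC Cq − 3.32. The LLOQ is the lowest-concentration
    calibrator whose mean Cq is below NTC+10 and above the mean Cq of the
    next-higher-concentration calibrator (a local monotonicity guard: a
    point whose signal does not fall back into place relative to its
    neighbor is still in the noise floor). The top calibrator has no
    higher neighbor and is never a candidate.

Node 2 — NTC undetermined and at least one calibrator undetermined:
    the highest undetermined calibrator concentration is the noise floor;
    the LLOQ is the measured calibrator nearest (in log10 concentration)
    to 10x that floor.

Node 3 — NTC undetermined, every calibrator determined:
    the hypothetical next-lower dilution (lowest concentration divided by
    the dilution factor) is taken as the detection floor; the LLOQ is the
    measured calibrator nearest to 10x that value.

Exactly one node fires per run; the path taken is recorded in the result.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .types import CalibrationRun, CalibratorDiagnostic, LloqResult

__all__ = ["cq_offset_for_fold", "lloq_baseline_noise", "nearest_concentration"]


def cq_offset_for_fold(fold: float) -> float:
    """Cq cycles equivalent to a given fold-change in template, assuming a
    doubling of product per cycle: log2(fold). A 10-fold change is 3.32 Cq."""
    if fold <= 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    return math.log2(fold)


def nearest_concentration(
    candidates: Sequence[float], target: float, tie_break: str = "high"
) -> float:
    """Candidate concentration nearest to target in |log10| distance.

    Serial dilutions are geometric, so distance is measured on the log
    scale. Ties go to the higher concentration by default (the
    conservative choice); tie_break="low" flips that.
    """
    if not candidates:
        raise ValueError("no candidate concentrations")
    if tie_break not in ("high", "low"):
        raise ValueError(f"tie_break must be 'high' or 'low', got {tie_break!r}")
    lt = math.log10(target)
    best: Optional[float] = None
    best_d = math.inf
    for conc in candidates:
        d = abs(math.log10(conc) - lt)
        if d < best_d - 1e-12:
            best, best_d = conc, d
        elif abs(d - best_d) <= 1e-12 and best is not None:
            take_higher = tie_break == "high"
            if (conc > best) == take_higher:
                best = conc
    return best


def lloq_baseline_noise(
    run: CalibrationRun,
    fold: float = 10.0,
    undetermined_policy: str = "all",
    tie_break: str = "high",
) -> LloqResult:
    """Route a run through the baseline-noise decision tree.

    Requires at least two calibrators and an NTC set. fold is the
    signal-to-noise multiple defining quantifiability (10 by default,
    giving the 3.32-Cq NTC offset).
    """
    if run.ntc is None:
        raise ValueError(f"run {run.run_id}: baseline-noise LLOQ requires an NTC set")
    if len(run.calibrators) < 2:
        raise ValueError(f"run {run.run_id}: need at least 2 calibrators")

    concs = run.concentrations

    if run.ntc.determined:
        # Node 1
        offset = cq_offset_for_fold(fold)
        ntc_plus = run.ntc.mean_cq - offset
        diagnostics: list[CalibratorDiagnostic] = []
        lloq: Optional[float] = None
        for i, point in enumerate(run.calibrators):
            if i == len(run.calibrators) - 1:
                diagnostics.append(CalibratorDiagnostic(point.concentration, point.mean_cq, False))
                continue  # top calibrator: no higher neighbor, never a candidate
            mean = point.mean_cq
            next_mean = run.calibrators[i + 1].mean_cq
            ok = (
                mean is not None
                and next_mean is not None
                and mean < ntc_plus
                and mean > next_mean
            )
            diagnostics.append(CalibratorDiagnostic(point.concentration, mean, ok))
            if ok and lloq is None:
                lloq = point.concentration
        return LloqResult(
            lloq_amol_per_l=lloq,
            method="baseline_noise",
            decision_path="node1",
            per_calibrator=diagnostics,
            threshold_used=ntc_plus,
            run_id=run.run_id,
            notes="" if lloq is not None else "no calibrator below NTC+10 with monotone neighbor",
        )

    undetermined = [
        p.concentration for p in run.calibrators if p.is_undetermined(undetermined_policy)
    ]
    if undetermined:
        # Node 2: noise floor at the highest wholly-undetermined dilution
        floor = max(undetermined)
        target = fold * floor
        lloq = nearest_concentration(concs, target, tie_break)
        return LloqResult(
            lloq_amol_per_l=lloq,
            method="baseline_noise",
            decision_path="node2",
            threshold_used=target,
            run_id=run.run_id,
            notes=f"noise floor {floor:g} amol/L (highest undetermined calibrator)",
        )

    # Node 3: hypothetical next dilution below the measured series
    floor = run.lowest_concentration / run.dilution_factor
    target = fold * floor
    lloq = nearest_concentration(concs, target, tie_break)
    return LloqResult(
        lloq_amol_per_l=lloq,
        method="baseline_noise",
        decision_path="node3",
        threshold_used=target,
        run_id=run.run_id,
        notes=f"hypothetical next dilution {floor:g} amol/L",
    )
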