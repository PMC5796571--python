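"""Core domain types for qPCR calibration runs.

A run is one assay plate's worth of data: a serial-dilution calibration
series, a no-template control (NTC), and optionally unknown samples. Cq
values may be censored ("undetermined") when the amplification curve never
crosses threshold within the instrument's cycle ceiling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "CqValue",
    "CalibratorPoint",
    "NtcSet",
    "CalibrationRun",
    "LloqResult",
    "CalibratorDiagnostic",
]


@dataclass(frozen=True)
class CqValue:
    """A quantification-cycle measurement: a finite non-negative real, or censored.

    Censored values (the instrument's "undetermined" call) never enter
    arithmetic means; they mark reactions whose amplification curve stayed
    below threshold for the whole run.
    """

    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value is not None:
            v = float(self.value)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"Cq must be finite and non-negative, got {self.value!r}")
            object.__setattr__(self, "value", v)

    @property
    def censored(self) -> bool:
        return self.value is None

    @classmethod
    def undetermined(cls) -> "CqValue":
        return cls(None)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "CqValue(undetermined)" if self.censored else f"CqValue({self.value:g})"


def mean_cq(cqs: Iterable[CqValue]) -> Optional[float]:
    """Mean over non-censored replicates; None if every replicate is censored."""
    vals = [c.value for c in cqs if not c.censored]
    if not vals:
        return None
    return float(sum(vals) / len(vals))


@dataclass(frozen=True)
class CalibratorPoint:
    """One dilution of the calibration series.

    concentration is in amol/L; replicate_cqs are the PCR replicates at that
    dilution, in plate order.
    """

    concentration: float
    replicate_cqs: tuple[CqValue, ...]

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"calibrator concentration must be > 0, got {self.concentration}")
        if len(self.replicate_cqs) < 1:
            raise ValueError("calibrator needs at least one replicate Cq")
        object.__setattr__(self, "replicate_cqs", tuple(self.replicate_cqs))

    @property
    def mean_cq(self) -> Optional[float]:
        return mean_cq(self.replicate_cqs)

    @property
    def log10_concentration(self) -> float:
        return math.log10(self.concentration)

    def is_undetermined(self, policy: str = "all") -> bool:
        """Whether this point counts as an "undetermined" dilution.

        policy="all": every replicate censored (default).
        policy="majority": more than half of the replicates censored.
        """
        n_cens = sum(1 for c in self.replicate_cqs if c.censored)
        if policy == "all":
            return n_cens == len(self.replicate_cqs)
        if policy == "majority":
            return n_cens > len(self.replicate_cqs) / 2
        raise ValueError(f"unknown undetermined policy {policy!r}")


@dataclass(frozen=True)
class NtcSet:
    """No-template-control replicates for one run."""

    replicate_cqs: tuple[CqValue, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_cqs) < 1:
            raise ValueError("NTC set needs at least one replicate")
        object.__setattr__(self, "replicate_cqs", tuple(self.replicate_cqs))

    @property
    def determined(self) -> bool:
        """True iff at least one replicate produced a Cq (background signal present)."""
        return any(not c.censored for c in self.replicate_cqs)

    @property
    def mean_cq(self) -> Optional[float]:
        return mean_cq(self.replicate_cqs)


@dataclass
class CalibrationRun:
    """One assay run: ordered calibrators, an NTC, optional unknowns, metadata."""

    run_id: str
    calibrators: list[CalibratorPoint]
    ntc: Optional[NtcSet] = None
    unknowns: list[tuple[str, CqValue]] = field(default_factory=list)
    site: str = ""
    multiplicity: str = ""
    dilution_factor: float = 3.0

    def __post_init__(self) -> None:
        self.calibrators = sorted(self.calibrators, key=lambda p: p.concentration)
        concs = [p.concentration for p in self.calibrators]
        if len(set(concs)) != len(concs):
            raise ValueError(f"run {self.run_id}: duplicate calibrator concentrations")
        if self.dilution_factor <= 1:
            raise ValueError(f"dilution factor must exceed 1, got {self.dilution_factor}")
        for lo, hi in zip(concs, concs[1:]):
            ratio = hi / lo
            if abs(ratio / self.dilution_factor - 1.0) > 0.01:
                warnings.warn(
                    f"run {self.run_id}: calibrator step ratio {ratio:.3f} deviates from "
                    f"declared dilution factor {self.dilution_factor:g}",
                    stacklevel=2,
                )

    @property
    def concentrations(self) -> list[float]:
        return [p.concentration for p in self.calibrators]

    @property
    def lowest_concentration(self) -> float:
        return self.calibrators[0].concentration

    def n_usable_calibrators(self) -> int:
        """Calibrator points with at least one non-censored replicate."""
        return sum(1 for p in self.calibrators if p.mean_cq is not None)


@dataclass(frozen=True)
class CalibratorDiagnostic:
    """Per-calibrator metric evaluated during an LLOQ determination."""

    concentration: float
    metric: Optional[float]
    passed: bool


@dataclass
class LloqResult:
    """Outcome of one LLOQ determination on one run.

    lloq_amol_per_l is always a measured calibrator concentration of the run,
    or None when no calibrator qualifies (or the fit was indeterminate).
    """

    lloq_amol_per_l: Optional[float]
    method: str  # logistic_re | logistic_se | baseline_noise
    decision_path: str
    per_calibrator: list[CalibratorDiagnostic] = field(default_factory=list)
    threshold_used: Optional[float] = None
    run_id: str = ""
    notes: str = ""

    @property
    def missing(self) -> bool:
        return self.lloq_amol_per_l is None


def geometric_series(top: float, factor: float, n: int) -> list[float]:
    """Concentrations top/factor^k for k = n-1 … 0, ascending."""
    if top <= 0 or factor <= 1 or n < 1:
        raise ValueError("need top > 0, factor > 1, n >= 1")
    return [top / factor**k for k in range(n - 1, -1, -1)]
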