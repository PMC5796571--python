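"""Reading and writing the package's CSV dialects.

Input is a long-format table, one row per PCR well:

    run_id, site, multiplicity, sample_type, concentration_amol_per_L,
    replicate, cq, sample_id

sample_type is one of calibrator / ntc / unknown; concentration applies to
calibrators only; censored Cq cells carry an instrument token such as
"Undetermined". Output LLOQ tables carry one row per run and round-trip
at six significant digits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import RowParseError, SchemaError
from .types import CalibrationRun, CalibratorPoint, CqValue, LloqResult, NtcSet

__all__ = [
    "CsvSchema",
    "DEFAULT_CENSORED_TOKENS",
    "read_runs",
    "write_runs",
    "write_lloq_table",
    "read_lloq_table",
    "quantitations_to_frame",
]

DEFAULT_CENSORED_TOKENS = ("undetermined", "undet.", "na")

_REQUIRED = ["run_id", "site", "multiplicity", "sample_type", "concentration_amol_per_L", "replicate", "cq"]

_UNIT_TO_AMOL = {"amol/L": 1.0, "fmol/L": 1e3, "pmol/L": 1e6}


@dataclass(frozen=True)
class CsvSchema:
    """Column mapping and parsing conventions for input tables.

    columns maps the canonical names to the file's actual headers;
    censored_tokens are matched case-insensitively after stripping;
    concentration_unit converts the concentration column to amol/L.
    """

    columns: dict = field(default_factory=dict)
    censored_tokens: tuple[str, ...] = DEFAULT_CENSORED_TOKENS
    concentration_unit: str = "amol/L"
    dilution_factor: Optional[float] = None  # inferred from the series if None

    def actual(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _parse_cq(cell, tokens: Sequence[str], line: int) -> CqValue:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return CqValue.undetermined()
    text = str(cell).strip()
    if text == "" or text.lower() in tokens:
        return CqValue.undetermined()
    try:
        return CqValue(float(text))
    except ValueError as exc:
        raise RowParseError(f"unparseable Cq cell {cell!r}", line) from exc


def _infer_dilution_factor(concs: Sequence[float]) -> float:
    if len(concs) < 2:
        return 3.0
    ratios = [hi / lo for lo, hi in zip(concs, concs[1:])]
    ratios.sort()
    return ratios[len(ratios) // 2]


def read_runs(path: str | Path, schema: Optional[CsvSchema] = None) -> list[CalibrationRun]:
    """Parse a long-format well table into calibration runs.

    Every row is either consumed into a run or reported: unparseable cells
    raise RowParseError with the 1-based file line; a run ending up with
    fewer than two calibrator points is dropped with a warning naming it.
    """
    schema = schema or CsvSchema()
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {schema.actual(c): c for c in _REQUIRED + ["sample_id"]}
    missing = [schema.actual(c) for c in _REQUIRED if schema.actual(c) not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    df = df.rename(columns={k: v for k, v in colmap.items() if k in df.columns})
    if "sample_id" not in df.columns:
        df["sample_id"] = ""

    tokens = tuple(t.lower() for t in schema.censored_tokens)
    try:
        unit_scale = _UNIT_TO_AMOL[schema.concentration_unit]
    except KeyError:
        raise SchemaError(
            f"unknown concentration unit {schema.concentration_unit!r}; "
            f"supported: {sorted(_UNIT_TO_AMOL)}"
        )

    runs: list[CalibrationRun] = []
    # +2: header line plus 1-based indexing
    df["line_no"] = df.index + 2
    for run_id, group in df.groupby("run_id", sort=False):
        calib_reps: dict[float, list[tuple[int, CqValue]]] = {}
        ntc_reps: list[tuple[int, CqValue]] = []
        unknowns: list[tuple[str, CqValue]] = []
        site = group["site"].iloc[0]
        multiplicity = group["multiplicity"].iloc[0]
        for row in group.itertuples(index=False):
            line = row.line_no
            kind = str(row.sample_type).strip().lower()
            cq = _parse_cq(row.cq, tokens, line)
            if kind == "calibrator":
                raw = str(row.concentration_amol_per_L).strip()
                try:
                    conc = float(raw) * unit_scale
                except ValueError as exc:
                    raise RowParseError(f"unparseable concentration {raw!r}", line) from exc
                if conc <= 0:
                    raise RowParseError(f"calibrator concentration must be > 0, got {raw}", line)
                try:
                    rep = int(float(row.replicate))
                except ValueError as exc:
                    raise RowParseError(f"unparseable replicate index {row.replicate!r}", line) from exc
                calib_reps.setdefault(conc, []).append((rep, cq))
            elif kind == "ntc":
                ntc_reps.append((int(float(row.replicate or 1)), cq))
            elif kind == "unknown":
                sid = str(row.sample_id).strip() or f"{run_id}-unknown"
                unknowns.append((sid, cq))
            else:
                raise RowParseError(f"unknown sample_type {row.sample_type!r}", line)

        if len(calib_reps) < 2:
            warnings.warn(
                f"run {run_id!r} rejected: only {len(calib_reps)} calibrator point(s)",
                stacklevel=2,
            )
            continue
        concs = sorted(calib_reps)
        calibrators = [
            CalibratorPoint(c, tuple(cq for _, cq in sorted(calib_reps[c], key=lambda t: t[0])))
            for c in concs
        ]
        ntc = (
            NtcSet(tuple(cq for _, cq in sorted(ntc_reps, key=lambda t: t[0])))
            if ntc_reps
            else None
        )
        factor = schema.dilution_factor or _infer_dilution_factor(concs)
        runs.append(
            CalibrationRun(
                run_id=str(run_id),
                site=str(site),
                multiplicity=str(multiplicity),
                dilution_factor=factor,
                calibrators=calibrators,
                ntc=ntc,
                unknowns=unknowns,
            )
        )
    return runs


def write_runs(runs: Iterable[CalibrationRun], path: str | Path) -> None:
    """Serialize runs to the long-format input dialect (inverse of read_runs)."""
    rows = []
    for run in runs:
        base = {"run_id": run.run_id, "site": run.site, "multiplicity": run.multiplicity}
        for point in run.calibrators:
            for i, cq in enumerate(point.replicate_cqs, start=1):
                rows.append(
                    base
                    | {
                        "sample_type": "calibrator",
                        "concentration_amol_per_L": f"{point.concentration:.6g}",
                        "replicate": i,
                        "cq": "Undetermined" if cq.censored else f"{cq.value:.4f}",
                        "sample_id": "",
                    }
                )
        if run.ntc is not None:
            for i, cq in enumerate(run.ntc.replicate_cqs, start=1):
                rows.append(
                    base
                    | {
                        "sample_type": "ntc",
                        "concentration_amol_per_L": "",
                        "replicate": i,
                        "cq": "Undetermined" if cq.censored else f"{cq.value:.4f}",
                        "sample_id": "",
                    }
                )
        for sid, cq in run.unknowns:
            rows.append(
                base
                | {
                    "sample_type": "unknown",
                    "concentration_amol_per_L": "",
                    "replicate": 1,
                    "cq": "Undetermined" if cq.censored else f"{cq.value:.4f}",
                    "sample_id": sid,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_lloq_table(results: Sequence[LloqResult], path: str | Path, meta: str = "") -> None:
    """One row per run: the LLOQ (blank when missing), the method, the
    decision path taken, and the threshold that drove it."""
    if not results:
        raise ValueError("no LLOQ results to write")
    rows = [
        {
            "run_id": r.run_id,
            "method": r.method,
            "decision_path": r.decision_path if not r.missing or r.decision_path else "indeterminate",
            "lloq_amol_per_L": "" if r.missing else f"{r.lloq_amol_per_l:.6g}",
            "threshold_used": "" if r.threshold_used is None else f"{r.threshold_used:.6g}",
            "notes": r.notes,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        frame.to_csv(fh, index=False)


def read_lloq_table(path: str | Path) -> list[LloqResult]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    out = []
    for row in df.itertuples(index=False):
        val = str(row.lloq_amol_per_L).strip()
        thr = str(row.threshold_used).strip()
        out.append(
            LloqResult(
                lloq_amol_per_l=float(val) if val else None,
                method=row.method,
                decision_path=row.decision_path,
                threshold_used=float(thr) if thr else None,
                run_id=row.run_id,
                notes=row.notes,
            )
        )
    return out


def quantitations_to_frame(quants) -> pd.DataFrame:
    """Sample quantitations as a tidy frame (one row per sample)."""
    return pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "run_id": q.run_id,
                "copies_per_uL": q.copies_per_ul,
                "ci95_low": q.ci95_low,
                "ci95_high": q.ci95_high,
                "lloq_copies_per_uL": q.lloq_copies_per_ul,
                "below_lloq": q.below_lloq,
                "lloq_method": q.lloq_method,
                "n_replicates": q.n_replicates,
                "notes": q.notes,
            }
            for q in quants
        ]
    )
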