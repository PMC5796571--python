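"""Run-time configuration shared by the CLI and the pipeline helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["Config", "load_config", "config_hash"]


@dataclass
class Config:
    """Every tunable threshold and policy in one place.

    re_threshold: percent relative error below which a calibrator passes (20).
    se_threshold: inverse-prediction SE bound, log10-concentration units (0.25).
    se_scale: scale the SE threshold lives on, "log10" or "ln".
    fold: signal-to-noise multiple defining the baseline-noise LLOQ (10).
    tie_break: which calibrator wins a nearest-point tie, "high" or "low".
    undetermined_policy: when a calibrator counts as undetermined,
        "all" replicates censored or a "majority".
    censor_ceiling: instrument cycle ceiling for simulation (40).
    dilution_factor: declared step ratio of the series (3).
    include_new_observation: keep the replicate-noise term in the
        inverse-prediction variance (prediction- vs confidence-interval mode).
    volume_factor: µL biofluid per µL reaction for copies/µL conversion.
    """

    re_threshold: float = 20.0
    se_threshold: float = 0.25
    se_scale: str = "log10"
    fold: float = 10.0
    tie_break: str = "high"
    undetermined_policy: str = "all"
    censor_ceiling: float = 40.0
    dilution_factor: float = 3.0
    include_new_observation: bool = True
    volume_factor: float = 1.0

    def lloq_kwargs(self) -> dict:
        return {
            "re_threshold": self.re_threshold,
            "se_threshold": self.se_threshold,
            "se_scale": self.se_scale,
            "tie_break": self.tie_break,
            "undetermined_policy": self.undetermined_policy,
        }


def load_config(path: Optional[str | Path] = None, **overrides) -> Config:
    """Build a Config from an optional YAML file plus keyword overrides
    (command-line flags override the file; unknown keys are rejected)."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return Config(**data)


def config_hash(cfg: Config) -> str:
    """Short stable digest of a configuration, stamped into outputs."""
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
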