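"""Analysis configuration with the study's default thresholds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the calling pipeline.

    Defaults: housekeeping-geomean QC gate at 100 raw counts; log base 2
    (calls are base-invariant); skipping cutoff mean + 2.SD with strict '>';
    expression tiers at mean + 1.SD and mean + 2.SD with '>=' boundaries;
    zero raw junction counts are directly negative (``raw_zero``).
    """

    qc_hk_geomean_min: float = 100.0
    log_base: float | str = 2
    lr_k: float = 2.0
    lm_k_mod: float = 1.0
    lm_k_high: float = 2.0
    detect_mode: str = "raw_zero"
    strict_gt: bool = True
    ci_method: str = "wilson"
    ci_conf: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        # accept dotted keys like "qc.hk_geomean_min" as well as flat ones
        known = {f.name for f in cls.__dataclass_fields__.values()}
        flat = {}
        for key, val in data.items():
            if isinstance(val, dict):
                for sub, v in val.items():
                    # accept either the prefixed ("qc_hk_geomean_min") or the
                    # bare ("lr_k") field name under a section header
                    name = f"{key}_{sub}" if f"{key}_{sub}" in known else sub
                    flat[name] = v
            elif val is not None:
                flat[key.replace(".", "_")] = val
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**flat)

    def as_dict(self) -> dict:
        return asdict(self)
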