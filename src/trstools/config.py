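"""Declarative run configuration and cross-reference validation."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .distributions import FAMILY_ORDER

__all__ = ["CalibrationEntry", "RunConfig", "load_config", "validate_config"]


class CalibrationEntry(BaseModel):
    """The reference species' observed acute calibration datum."""

    species: str
    ec_measured: float = Field(gt=0)  # µg/L
    measured_day: float = Field(gt=0)  # days


class RunConfig(BaseModel):
    """Everything a reproducible end-to-end run needs.

    Paths are resolved relative to the config file's directory when
    loaded through :func:`load_config`.
    """

    toxicity_csv: str
    timeseries_csv: str
    acr_table_csv: Optional[str] = None

    class_map: Dict[str, str]  # data class -> reference class | "exclude"
    calibration: Dict[str, CalibrationEntry]  # reference class -> datum

    protection_levels: List[float] = [99.0, 95.0, 90.0, 80.0]
    day_start: int = 1
    day_end: int = 100
    families: List[str] = list(FAMILY_ORDER)
    forced_family: Dict[int, str] = {}

    min_purity: float = 80.0
    min_quality: float = 50.0
    acute_divisor: float = 5.0
    medium: Optional[str] = None  # optional freshwater/marine filter

    acr_scenarios: List[float] = []  # scalar ACRs, e.g. [10, 50, 100]
    use_acr_table: bool = False  # add the literature per-class scenario
    comparison_days: List[int] = [7, 14, 21, 28]

    n_boot_pc: int = 10_000
    n_boot_regression: int = 1000
    min_fit_size: int = 8
    cooks_threshold: Optional[float] = 1.0
    seed: int = 0
    output_dir: str = "trs_output"

    @field_validator("protection_levels")
    @classmethod
    def _levels_in_range(cls, v):
        for p in v:
            if not (0 < p < 100):
                raise ValueError(f"protection level {p} outside (0, 100)")
        return v

    @field_validator("families")
    @classmethod
    def _known_families(cls, v):
        unknown = set(v) - set(FAMILY_ORDER)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        return v


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML (or JSON) config, resolving paths against its directory."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    base = path.parent
    for attr in ("toxicity_csv", "timeseries_csv", "acr_table_csv", "output_dir"):
        value = getattr(cfg, attr)
        if value is not None and not Path(value).is_absolute():
            setattr(cfg, attr, str(base / value))
    return cfg


def validate_config(config: RunConfig) -> List[str]:
    """Check every cross-reference; returns ALL failures, not just the first."""
    failures: List[str] = []
    for attr in ("toxicity_csv", "timeseries_csv", "acr_table_csv"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            failures.append(f"{attr}: file not found: {p}")
    if config.day_end < config.day_start:
        failures.append(
            f"empty day range: day_start={config.day_start}, day_end={config.day_end}"
        )
    if any(d < config.day_start or d > config.day_end for d in config.comparison_days):
        failures.append("comparison_days outside the configured day range")
    if (config.n_boot_pc > 0 or config.n_boot_regression > 0) and config.seed is None:
        failures.append("seed required when any bootstrap size > 0")
    for refclass in set(config.class_map.values()) - {"exclude"}:
        if refclass not in config.calibration:
            failures.append(
                f"class_map references reference class {refclass!r} "
                "with no calibration entry"
            )
    for day in config.forced_family:
        if not (config.day_start <= day <= config.day_end):
            failures.append(f"forced_family day {day} outside the day range")

    # cross-check against the data files where they exist
    if Path(config.toxicity_csv).exists():
        try:
            df = pd.read_csv(config.toxicity_csv)
            if "class" in df.columns:
                data_classes = set(df["class"].astype(str).str.strip())
                unmapped = data_classes - set(config.class_map)
                if unmapped:
                    failures.append(
                        f"taxon classes present in data but absent from class_map: "
                        f"{sorted(unmapped)}"
                    )
        except Exception as exc:
            failures.append(f"toxicity_csv unreadable: {exc}")
    if Path(config.timeseries_csv).exists():
        try:
            ts = pd.read_csv(config.timeseries_csv)
            if "class" in ts.columns:
                ts_classes = set(ts["class"].astype(str).str.strip())
                for refclass in config.calibration:
                    if refclass not in ts_classes:
                        failures.append(
                            f"calibration class {refclass!r} has no reference "
                            "time series"
                        )
        except Exception as exc:
            failures.append(f"timeseries_csv unreadable: {exc}")
    return failures
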