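"""End-to-end reproducible runs: data → models → TAFs → surface → exports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import acr as acr_mod
from .config import RunConfig, validate_config
from .records import (
    SpeciesSensitivitySet,
    aggregate_species,
    convert_record,
    read_toxicity_table,
    screen_records,
)
from .ssd import DEFAULT_PROTECTION_LEVELS
from .surface import TRSSurface, build_trs, export_trs_table
from .timetox import TimeResponseRegressor, fit_time_response, read_time_series

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifact bundle from one pipeline run."""

    surface: TRSSurface
    models: Dict[str, TimeResponseRegressor]
    acute_set: SpeciesSensitivitySet
    chronic_set: SpeciesSensitivitySet
    scenarios: List = field(default_factory=list)
    comparison: Optional[pd.DataFrame] = None
    output_dir: Optional[Path] = None
    log: List[str] = field(default_factory=list)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full workflow described by ``config``.

    Stages: read → screen → acute/chronic split (+ acute-to-chronic
    division) → per-species aggregation → reference regression fits →
    TAF tables → TRS assembly → exports (+ ACR comparison when
    configured). Identical config + seed yields byte-identical exports;
    the run log records every exclusion, removal, and selection.
    """
    failures = validate_config(config)
    if failures:
        raise ValueError("config validation failed:\n" + "\n".join(failures))
    log: List[str] = [f"config_hash_inputs seed={config.seed}"]

    records = read_toxicity_table(config.toxicity_csv)
    if config.medium:
        before = len(records)
        records = [r for r in records if r.medium == config.medium]
        log.append(f"medium filter {config.medium!r}: {before} -> {len(records)}")
    kept, report = screen_records(records, config.min_purity, config.min_quality)
    for _, row in report[report["disposition"] == "excluded"].iterrows():
        log.append(f"excluded record {row['index']} ({row['species']}): {row['rule']}")

    acute_records = [
        convert_record(r, config.acute_divisor)
        for r in kept
        if r.effect_type == "acute"
    ]
    chronic_records = [r for r in kept if r.effect_type == "chronic"]
    log.append(
        f"screened: {len(kept)} kept ({len(acute_records)} acute, "
        f"{len(chronic_records)} chronic); acute divided by {config.acute_divisor}"
    )
    acute_set = aggregate_species(acute_records)
    chronic_set = (
        aggregate_species(chronic_records)
        if chronic_records
        else SpeciesSensitivitySet()
    )

    series = read_time_series(config.timeseries_csv)
    models: Dict[str, TimeResponseRegressor] = {}
    for species, (taxon_class, points) in series.items():
        model = fit_time_response(points, cooks_threshold=config.cooks_threshold)
        models[taxon_class] = model
        log.append(
            f"time-response fit {species} ({taxon_class}): slope={model.slope_:.4f} "
            f"D2={model.dsquared_:.4f} removed={model.removed_points_}"
        )

    surface = build_trs(
        acute_set,
        models=models,
        calibration={k: v.model_dump() for k, v in config.calibration.items()},
        class_map=config.class_map,
        days=range(config.day_start, config.day_end + 1),
        protection_levels=config.protection_levels,
        families=config.families,
        forced_family=config.forced_family or None,
        n_boot=config.n_boot_pc,
        seed=config.seed,
        min_fit_size=config.min_fit_size,
    )
    for day, fam in surface.family_switch_days():
        log.append(f"family selection: day {day} -> {fam}")

    scenarios = []
    for a in config.acr_scenarios:
        scenarios.append(
            acr_mod.apply_acr_scenario(
                chronic_set,
                acute_set_unconverted(kept, config),
                acr=a,
                families=config.families,
                protection_levels=config.protection_levels,
                n_boot=config.n_boot_pc,
                seed=config.seed + 1 + int(a),
                min_fit_size=config.min_fit_size,
            )
        )
    if config.use_acr_table and config.acr_table_csv:
        table = acr_mod.read_acr_table(config.acr_table_csv)
        mapping = dict(zip(table["taxon_class"], table["acr"]))
        scenarios.append(
            acr_mod.apply_acr_scenario(
                chronic_set,
                acute_set_unconverted(kept, config),
                acr=mapping,
                name="ACR_lit",
                families=config.families,
                protection_levels=config.protection_levels,
                n_boot=config.n_boot_pc,
                seed=config.seed + 997,
                min_fit_size=config.min_fit_size,
            )
        )
    comparison = (
        acr_mod.compare_with_trs(scenarios, surface, config.comparison_days)
        if scenarios
        else None
    )

    result = PipelineResult(
        surface=surface,
        models=models,
        acute_set=acute_set,
        chronic_set=chronic_set,
        scenarios=scenarios,
        comparison=comparison,
        log=log,
    )
    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        export_trs_table(surface, out / "trs_table.csv")
        report.to_csv(out / "screening_report.csv", index=False)
        with open(out / "model_reports.json", "w") as fh:
            fh.write(
                json.dumps(
                    {cls: json.loads(m.to_json()) for cls, m in models.items()},
                    sort_keys=True,
                    indent=2,
                )
            )
        with open(out / "surface.json", "w") as fh:
            fh.write(
                json.dumps(
                    {
                        "provenance": surface.provenance,
                        "days": surface.days,
                        "families": {
                            str(d): surface.slices[d].fit.family for d in surface.days
                        },
                    },
                    sort_keys=True,
                    indent=2,
                )
            )
        if comparison is not None:
            comparison.to_csv(out / "acr_comparison.csv", index=False)
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log) + "\n")
        result.output_dir = out
    return result


def acute_set_unconverted(kept_records, config: RunConfig) -> SpeciesSensitivitySet:
    """Aggregate the screened acute records without the /divisor conversion
    (ACR scenarios divide by their own ratio instead)."""
    return aggregate_species([r for r in kept_records if r.effect_type == "acute"])
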