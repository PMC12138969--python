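"""Acute-to-chronic-ratio SSD scenarios and comparison with the TRS.

The conventional route from acute data to a chronic guideline divides
each acute value by an acute-to-chronic ratio (ACR) — a fixed scalar
(default guidance values of 10, 50, or 100) or literature-derived
per-class ratios — then pools the converted values with observed
chronic data and fits an SSD. These scenarios are the yardstick the
duration-resolved TRS protective concentrations are compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .distributions import FAMILY_ORDER
from .records import SpeciesEntry, SpeciesSensitivitySet
from .ssd import (
    DEFAULT_PROTECTION_LEVELS,
    PCEstimate,
    SSDFit,
    bootstrap_ci,
    fit_all_families,
    protective_concentration,
    select_distribution,
)
from .surface import TRSSurface

__all__ = [
    "ACRScenario",
    "apply_acr_scenario",
    "compare_with_trs",
    "read_acr_table",
    "acr_geomeans_by_class",
]

ACRValue = Union[float, Mapping[str, float]]


@dataclass
class ACRScenario:
    """One ACR-adjusted SSD: converted acute + untouched chronic values."""

    name: str
    acr_values: ACRValue
    combined_set: SpeciesSensitivitySet
    fit: SSDFit
    pcs: Dict[float, PCEstimate] = field(default_factory=dict)


def _acr_for(entry: SpeciesEntry, acr: ACRValue) -> float:
    if isinstance(acr, Mapping):
        if entry.taxon_class not in acr:
            raise ValueError(
                f"per-class ACR mapping has no entry for class {entry.taxon_class!r}"
            )
        value = float(acr[entry.taxon_class])
    else:
        value = float(acr)
    if value <= 0:
        raise ValueError(f"ACR must be > 0, got {value}")
    return value


def apply_acr_scenario(
    chronic: SpeciesSensitivitySet,
    acute: SpeciesSensitivitySet,
    acr: ACRValue,
    name: str = "",
    families: Sequence[str] = FAMILY_ORDER,
    protection_levels: Sequence[float] = DEFAULT_PROTECTION_LEVELS,
    n_boot: int = 0,
    seed: int = 0,
    min_fit_size: int = 8,
) -> ACRScenario:
    """Convert acute values by ACR, pool with chronic data, fit the SSD.

    Chronic values pass through unmodified and take precedence when a
    species appears in both sets.
    """
    entries: Dict[str, SpeciesEntry] = {}
    for sp, e in acute.entries.items():
        entries[sp] = replace(
            e, value=e.value / _acr_for(e, acr), value_kind="acute_estimated"
        )
    for sp, e in chronic.entries.items():
        entries[sp] = replace(e, value_kind="chronic_observed")
    combined = SpeciesSensitivitySet(entries=entries)
    values = combined.values()
    fits, failures = fit_all_families(values, families, min_fit_size=min_fit_size)
    if not fits:
        raise RuntimeError(f"no family converged for ACR scenario {name!r}: {failures}")
    fit = select_distribution(fits)
    if n_boot > 0:
        pcs = {
            e.protection_pct: e
            for e in bootstrap_ci(
                values,
                fit.family,
                protection_pcts=protection_levels,
                n_boot=n_boot,
                seed=seed,
                min_fit_size=min_fit_size,
            )
        }
    else:
        pcs = {
            float(p): PCEstimate(
                protection_pct=float(p),
                point=protective_concentration(fit, p),
                ci_lower=protective_concentration(fit, p),
                ci_upper=protective_concentration(fit, p),
                n_boot=0,
            )
            for p in protection_levels
        }
    return ACRScenario(
        name=name or (f"ACR{acr:g}" if not isinstance(acr, Mapping) else "ACR_lit"),
        acr_values=acr,
        combined_set=combined,
        fit=fit,
        pcs=pcs,
    )


def compare_with_trs(
    scenarios: Sequence[ACRScenario],
    surface: TRSSurface,
    days: Sequence[int],
    protection_levels: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Tabulate scenario PCs against TRS PCs at chosen exposure days.

    One row per (protection level, scenario, TRS day) pair, with the
    ratio scenario PC / TRS PC.
    """
    levels = tuple(protection_levels or surface.protection_levels)
    rows = []
    for level in levels:
        for scen in scenarios:
            if level not in scen.pcs:
                raise ValueError(
                    f"scenario {scen.name!r} lacks protection level {level}"
                )
            for d in days:
                trs_pc = surface.slice(d).pcs[float(level)].point
                sc_pc = scen.pcs[level].point
                rows.append(
                    {
                        "protection_pct": level,
                        "scenario": scen.name,
                        "scenario_pc": sc_pc,
                        "trs_day": int(d),
                        "trs_pc": trs_pc,
                        "ratio_scenario_over_trs": sc_pc / trs_pc,
                    }
                )
    return pd.DataFrame(rows)


def read_acr_table(source) -> pd.DataFrame:
    """Read a per-class ACR table.

    Columns: taxon_class, acr, acr_min, acr_max, source_id (min/max
    optional; they drive the high/low scenario bands).
    """
    df = pd.read_csv(source)
    required = {"taxon_class", "acr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ACR table missing columns: {sorted(missing)}")
    if (df["acr"] <= 0).any():
        raise ValueError("ACR values must be > 0")
    return df


def acr_geomeans_by_class(per_species: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw per-species ACRs to per-class geometric means.

    Input columns: taxon_class, species, acr. Output: taxon_class,
    acr (geomean), acr_min, acr_max.
    """
    required = {"taxon_class", "acr"}
    missing = required - set(per_species.columns)
    if missing:
        raise ValueError(f"per-species ACR table missing columns: {sorted(missing)}")
    if (per_species["acr"] <= 0).any():
        raise ValueError("ACR values must be > 0")
    grouped = per_species.groupby("taxon_class")["acr"]
    return pd.DataFrame(
        {
            "taxon_class": grouped.mean().index,
            "acr": np.exp(grouped.apply(lambda s: np.mean(np.log(s)))).values,
            "acr_min": grouped.min().values,
            "acr_max": grouped.max().values,
        }
    ).reset_index(drop=True)
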