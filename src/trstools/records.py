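"""Toxicity record ingestion, quality screening, and species aggregation.

One :class:`ToxicityRecord` is a single bioassay result — a species, its
taxonomic class, an endpoint (LC50, EC50, NOEC, EC10, LC10), an effect
concentration, and the exposure duration — normalized to canonical units
of µg/L and days at read time. Screening applies the purity and quality
rules used for water-quality guideline derivation (active ingredient
strictly above 80%, quality score at least 50%). Species with multiple
records are aggregated by geometric mean into a
:class:`SpeciesSensitivitySet`, the input to SSD fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ToxicityRecord",
    "SpeciesEntry",
    "SpeciesSensitivitySet",
    "SchemaError",
    "RecordValidationError",
    "DataIntegrityError",
    "CSV_COLUMNS",
    "read_toxicity_table",
    "write_toxicity_table",
    "screen_records",
    "acute_to_chronic_estimate",
    "aggregate_species",
]

VALID_ENDPOINTS = ("LC50", "EC50", "NOEC", "EC10", "LC10")
VALID_EFFECT_TYPES = ("acute", "chronic")
VALID_MEDIA = ("freshwater", "marine")

#: Canonical CSV schema (the bundled template, data/toxicity_template.csv).
CSV_COLUMNS = (
    "species",
    "class",
    "phylum",
    "medium",
    "endpoint",
    "effect_type",
    "concentration",
    "conc_unit",
    "duration",
    "duration_unit",
    "purity_pct",
    "quality_pct",
    "source_id",
)

_MANDATORY = (
    "species",
    "class",
    "endpoint",
    "concentration",
    "duration",
)


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class RecordValidationError(ValueError):
    """A row violates a domain invariant (reported with its row index)."""


class DataIntegrityError(ValueError):
    """Cross-record inconsistency, e.g. one species with two taxon classes."""


@dataclass(frozen=True)
class ToxicityRecord:
    """One bioassay result in canonical units (µg/L, days)."""

    species_name: str
    taxon_class: str
    phylum: str = ""
    medium: str = "freshwater"
    endpoint: str = "LC50"
    effect_type: str = "acute"
    concentration: float = 0.0  # µg/L
    duration: float = 0.0  # days
    purity_pct: float = 100.0
    quality_pct: float = 100.0
    source_id: str = ""
    value_kind: str = "measured"  # measured | acute_estimated


@dataclass(frozen=True)
class SpeciesEntry:
    value: float  # µg/L
    taxon_class: str
    medium: str
    n_source_records: int
    value_kind: str  # chronic_observed | acute_estimated


@dataclass
class SpeciesSensitivitySet:
    """One sensitivity value per species, ready for SSD fitting."""

    entries: Dict[str, SpeciesEntry] = field(default_factory=dict)

    def values(self) -> np.ndarray:
        return np.array([e.value for e in self.entries.values()], dtype=float)

    def species(self) -> List[str]:
        return list(self.entries)

    def classes(self) -> List[str]:
        return sorted({e.taxon_class for e in self.entries.values()})

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": sp,
                    "value_ugL": e.value,
                    "class": e.taxon_class,
                    "medium": e.medium,
                    "n_source_records": e.n_source_records,
                    "value_kind": e.value_kind,
                }
                for sp, e in self.entries.items()
            ]
        )


def _canonical_species(name: str) -> str:
    return " ".join(str(name).split()).lower()


_CONC_FACTORS = {"ug/l": 1.0, "µg/l": 1.0, "ugl": 1.0, "mg/l": 1000.0, "mgl": 1000.0,
                 "ng/l": 1e-3}
_DUR_FACTORS = {"d": 1.0, "day": 1.0, "days": 1.0, "h": 1 / 24.0, "hr": 1 / 24.0,
                "hours": 1 / 24.0, "hour": 1 / 24.0}


def read_toxicity_table(
    source: TextIO | str,
    schema: Optional[Mapping[str, str]] = None,
) -> List[ToxicityRecord]:
    """Read bioassay records from delimited text, normalizing units.

    ``schema`` optionally maps canonical column names to the file's
    column names. Concentrations declared in mg/L are multiplied by
    1000; durations declared in hours are divided by 24. Row order is
    preserved.
    """
    df = pd.read_csv(source)
    colmap = {k: k for k in CSV_COLUMNS}
    if schema:
        colmap.update(schema)
    for col in _MANDATORY:
        if colmap[col] not in df.columns:
            raise SchemaError(f"missing mandatory column {colmap[col]!r}")

    def get(row, col, default=None):
        name = colmap[col]
        if name in df.columns and not pd.isna(row[name]):
            return row[name]
        return default

    records: List[ToxicityRecord] = []
    for idx, row in df.iterrows():
        conc = float(get(row, "concentration"))
        dur = float(get(row, "duration"))
        conc_unit = str(get(row, "conc_unit", "ug/L")).strip().lower()
        dur_unit = str(get(row, "duration_unit", "days")).strip().lower()
        if conc_unit not in _CONC_FACTORS:
            raise RecordValidationError(f"row {idx}: unknown concentration unit {conc_unit!r}")
        if dur_unit not in _DUR_FACTORS:
            raise RecordValidationError(f"row {idx}: unknown duration unit {dur_unit!r}")
        conc *= _CONC_FACTORS[conc_unit]
        dur *= _DUR_FACTORS[dur_unit]
        if not (conc > 0):
            raise RecordValidationError(f"row {idx}: concentration must be > 0, got {conc}")
        if not (dur > 0):
            raise RecordValidationError(f"row {idx}: duration must be > 0, got {dur}")
        endpoint = str(get(row, "endpoint")).strip().upper()
        if endpoint not in VALID_ENDPOINTS:
            raise RecordValidationError(
                f"row {idx}: unknown endpoint {endpoint!r}; expected one of {VALID_ENDPOINTS}"
            )
        effect_type = str(get(row, "effect_type", "acute")).strip().lower()
        if effect_type not in VALID_EFFECT_TYPES:
            raise RecordValidationError(f"row {idx}: unknown effect_type {effect_type!r}")
        medium = str(get(row, "medium", "freshwater")).strip().lower()
        if medium not in VALID_MEDIA:
            raise RecordValidationError(f"row {idx}: unknown medium {medium!r}")
        records.append(
            ToxicityRecord(
                species_name=_canonical_species(get(row, "species")),
                taxon_class=str(get(row, "class")).strip(),
                phylum=str(get(row, "phylum", "")).strip(),
                medium=medium,
                endpoint=endpoint,
                effect_type=effect_type,
                concentration=conc,
                duration=dur,
                purity_pct=float(get(row, "purity_pct", 100.0)),
                quality_pct=float(get(row, "quality_pct", 100.0)),
                source_id=str(get(row, "source_id", "")),
            )
        )
    return records


def write_toxicity_table(records: Sequence[ToxicityRecord], destination) -> None:
    """Write records in the canonical schema (µg/L, days) at full precision."""
    df = pd.DataFrame(
        [
            {
                "species": r.species_name,
                "class": r.taxon_class,
                "phylum": r.phylum,
                "medium": r.medium,
                "endpoint": r.endpoint,
                "effect_type": r.effect_type,
                "concentration": repr(r.concentration),
                "conc_unit": "ug/L",
                "duration": repr(r.duration),
                "duration_unit": "days",
                "purity_pct": repr(r.purity_pct),
                "quality_pct": repr(r.quality_pct),
                "source_id": r.source_id,
            }
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )
    df.to_csv(destination, index=False)


def screen_records(
    records: Sequence[ToxicityRecord],
    min_purity: float = 80.0,
    min_quality: float = 50.0,
) -> Tuple[List[ToxicityRecord], pd.DataFrame]:
    """Apply purity and quality screening rules.

    A record is kept when ``purity_pct > min_purity`` (strict: "greater
    than 80% active ingredient") AND ``quality_pct >= min_quality``
    (inclusive: "acceptable" quality starts at 50%). Returns the kept
    records and a per-record disposition table naming the triggered
    rule for every exclusion.
    """
    kept: List[ToxicityRecord] = []
    rows = []
    for i, r in enumerate(records):
        rules = []
        if not (r.purity_pct > min_purity):
            rules.append("purity")
        if not (r.quality_pct >= min_quality):
            rules.append("quality")
        if rules:
            disposition = "excluded"
        else:
            disposition = "kept"
            kept.append(r)
        rows.append(
            {
                "index": i,
                "species": r.species_name,
                "source_id": r.source_id,
                "disposition": disposition,
                "rule": "+".join(rules),
            }
        )
    columns = ["index", "species", "source_id", "disposition", "rule"]
    return kept, pd.DataFrame(rows, columns=columns)


def acute_to_chronic_estimate(value: float, divisor: float = 5.0) -> float:
    """Convert an acute LC50/EC50 to an estimated LC10/EC10 by division.

    The default divisor of 5 is the conversion recommended for guideline
    derivation when chronic data are unavailable.
    """
    if divisor <= 0:
        raise ValueError(f"divisor must be > 0, got {divisor}")
    if value <= 0:
        raise ValueError(f"value must be > 0, got {value}")
    return value / divisor


def convert_record(record: ToxicityRecord, divisor: float = 5.0) -> ToxicityRecord:
    """Apply the acute-to-chronic division to a record, flagging provenance."""
    return replace(
        record,
        concentration=acute_to_chronic_estimate(record.concentration, divisor),
        value_kind="acute_estimated",
    )


def aggregate_species(records: Sequence[ToxicityRecord]) -> SpeciesSensitivitySet:
    """Geometric-mean aggregation of per-species values.

    Species with several records receive the geometric mean of their
    concentrations (equivalently the exponentiated arithmetic mean of
    natural logs). Taxonomy and medium must be consistent within a
    species.
    """
    by_species: Dict[str, List[ToxicityRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_name, []).append(r)
    entries: Dict[str, SpeciesEntry] = {}
    for sp, recs in by_species.items():
        classes = {r.taxon_class for r in recs}
        if len(classes) > 1:
            raise DataIntegrityError(
                f"species {sp!r} has inconsistent taxon classes: {sorted(classes)}"
            )
        media = {r.medium for r in recs}
        if len(media) > 1:
            raise DataIntegrityError(
                f"species {sp!r} has inconsistent media: {sorted(media)}"
            )
        logs = [math.log(r.concentration) for r in recs]
        value = math.exp(sum(logs) / len(logs))
        kinds = {r.value_kind for r in recs}
        kind = "acute_estimated" if "acute_estimated" in kinds else "chronic_observed"
        entries[sp] = SpeciesEntry(
            value=value,
            taxon_class=recs[0].taxon_class,
            medium=recs[0].medium,
            n_source_records=len(recs),
            value_kind=kind,
        )
    return SpeciesSensitivitySet(entries=entries)
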