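"""Temporal adjustment factors and the temporal response surface.

A temporal adjustment factor (TAF) is the day-indexed analogue of an
acute-to-chronic ratio: for a reference species with a fitted time
response model, ``TAF(d) = EC_modelled(d) / EC_measured``, where
``EC_measured`` is the species' observed acute effect concentration at
its standard test duration. Applied multiplicatively per taxonomic
class, ``adjusted_EC(d) = EC * TAF(d)``, it rescales every acute value
in a community toxicity set to an arbitrary exposure duration, so
adjusted values decline with duration when the reference slope is
negative.

Stacking the adjusted data sets for days 1..100, fitting an SSD to
each, and selecting a family per day yields the temporal response
surface (TRS): protective concentrations and affected fractions indexed
by both concentration and exposure duration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import SpeciesSensitivitySet
from .ssd import (
    DEFAULT_PROTECTION_LEVELS,
    PCEstimate,
    SSDFit,
    bootstrap_ci,
    fit_all_families,
    fraction_affected,
    protective_concentration,
    select_distribution,
)
from .distributions import FAMILY_ORDER
from .timetox import TimeResponseRegressor

__all__ = [
    "TAFTable",
    "AdjustedDataset",
    "DaySlice",
    "TRSSurface",
    "ClassMappingError",
    "SurfaceBuildError",
    "compute_taf_table",
    "adjust_toxicity",
    "build_trs",
    "query_surface",
    "first_day_below",
    "export_trs_table",
]

EXCLUDE = "exclude"


class ClassMappingError(ValueError):
    """A species' taxon class does not resolve through the class map."""


class SurfaceBuildError(RuntimeError):
    """No candidate family converged for some day of the surface."""


@dataclass(frozen=True)
class TAFTable:
    """Per-class temporal adjustment factors for days 1..max_day."""

    taxon_class: str
    reference_species: str
    ec_measured: float  # µg/L, the observed acute calibration datum
    measured_day: float  # days, the acute test duration
    factors: Dict[int, float]  # day -> TAF

    def factor(self, day: int) -> float:
        try:
            return self.factors[int(day)]
        except KeyError:
            raise ValueError(
                f"day {day} outside TAF table for class {self.taxon_class!r}"
            ) from None


@dataclass(frozen=True)
class AdjustedDataset:
    """Community toxicity values rescaled to one exposure day."""

    day: int
    entries: Dict[str, float]  # species -> adjusted value, µg/L

    def values(self) -> np.ndarray:
        return np.array(list(self.entries.values()), dtype=float)


@dataclass(frozen=True)
class DaySlice:
    day: int
    dataset: AdjustedDataset
    fit: SSDFit
    pcs: Dict[float, PCEstimate]  # protection level -> estimate


@dataclass
class TRSSurface:
    """The day-indexed stack of adjusted SSDs."""

    slices: Dict[int, DaySlice]
    protection_levels: Tuple[float, ...]
    provenance: Dict = field(default_factory=dict)

    @property
    def days(self) -> List[int]:
        return sorted(self.slices)

    def slice(self, day: int) -> DaySlice:
        try:
            return self.slices[int(day)]
        except KeyError:
            raise ValueError(f"day {day} outside surface (days {self.days[0]}..{self.days[-1]})") from None

    def family_switch_days(self) -> List[Tuple[int, str]]:
        """Days at which the selected family changes, with the new family."""
        out = []
        prev = None
        for d in self.days:
            fam = self.slices[d].fit.family
            if fam != prev:
                out.append((d, fam))
                prev = fam
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.days:
            s = self.slices[d]
            row = {"day": d, "family": s.fit.family, "n_species": s.fit.n}
            for level in self.protection_levels:
                pc = s.pcs[level]
                tag = f"pc{level:g}"
                row[tag] = pc.point
                row[f"{tag}_lower"] = pc.ci_lower
                row[f"{tag}_upper"] = pc.ci_upper
                row[f"{tag}_display"] = f"{pc.point:.2g}"
            rows.append(row)
        return pd.DataFrame(rows)


def compute_taf_table(
    model: TimeResponseRegressor,
    ec_measured: float,
    measured_day: float,
    taxon_class: str = "",
    reference_species: str = "",
    days: Sequence[int] = range(1, 101),
) -> TAFTable:
    """TAF(d) = modelled EC at day d / measured acute EC, for each day."""
    if model is None:
        raise ValueError(f"no time-response model configured for class {taxon_class!r}")
    if not ec_measured > 0:
        raise ValueError(f"ec_measured must be > 0, got {ec_measured}")
    day_list = [int(d) for d in days]
    preds = model.predict(np.asarray(day_list, dtype=float))
    return TAFTable(
        taxon_class=taxon_class,
        reference_species=reference_species,
        ec_measured=float(ec_measured),
        measured_day=float(measured_day),
        factors={d: float(p / ec_measured) for d, p in zip(day_list, preds)},
    )


def _resolve_class(taxon_class: str, class_map: Mapping[str, str]) -> str:
    if taxon_class not in class_map:
        raise ClassMappingError(
            f"taxon class {taxon_class!r} has no entry in class_map; map it to a "
            f"reference class or mark it {EXCLUDE!r} explicitly"
        )
    return class_map[taxon_class]


def adjust_toxicity(
    sens_set: SpeciesSensitivitySet,
    tafs: Mapping[str, TAFTable],
    class_map: Mapping[str, str],
    day: int,
) -> AdjustedDataset:
    """Rescale every species value to one exposure day via its class TAF.

    ``class_map`` maps each data class to a reference class with a TAF
    table, or to ``"exclude"``. Unmapped classes raise, listing the
    affected species — silent dropping is never performed.
    """
    unmapped = [
        sp
        for sp, e in sens_set.entries.items()
        if e.taxon_class not in class_map
    ]
    if unmapped:
        classes = sorted({sens_set.entries[sp].taxon_class for sp in unmapped})
        raise ClassMappingError(
            f"species with unmapped taxon classes {classes}: {sorted(unmapped)}; "
            f"add class_map entries (use {EXCLUDE!r} to drop them explicitly)"
        )
    entries = {}
    for sp, e in sens_set.entries.items():
        ref = class_map[e.taxon_class]
        if ref == EXCLUDE:
            continue
        if ref not in tafs:
            raise ClassMappingError(
                f"class {e.taxon_class!r} maps to reference class {ref!r} "
                "which has no TAF table"
            )
        entries[sp] = e.value * tafs[ref].factor(day)
    return AdjustedDataset(day=int(day), entries=entries)


def _config_hash(payload: Dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def build_trs(
    sens_set: SpeciesSensitivitySet,
    models: Mapping[str, TimeResponseRegressor],
    calibration: Mapping[str, Mapping[str, float]],
    class_map: Mapping[str, str],
    days: Sequence[int] = range(1, 101),
    protection_levels: Sequence[float] = DEFAULT_PROTECTION_LEVELS,
    families: Sequence[str] = FAMILY_ORDER,
    forced_family: Optional[Mapping[int, str]] = None,
    n_boot: int = 0,
    seed: int = 0,
    min_fit_size: int = 8,
) -> TRSSurface:
    """Assemble the temporal response surface.

    Parameters
    ----------
    models : reference class -> fitted :class:`TimeResponseRegressor`.
    calibration : reference class -> ``{"species", "ec_measured",
        "measured_day"}`` — the observed acute calibration datum; it is
        always supplied explicitly, never inferred.
    class_map : data class -> reference class (or ``"exclude"``).
    forced_family : optional day -> family override of AICc selection.
    n_boot : parametric-bootstrap size for PC confidence intervals;
        0 computes point estimates only (intervals set equal to the point).
    """
    day_list = [int(d) for d in days]
    if not day_list:
        raise ValueError("empty day range")
    tafs = {
        ref: compute_taf_table(
            models[ref],
            ec_measured=float(cal["ec_measured"]),
            measured_day=float(cal["measured_day"]),
            taxon_class=ref,
            reference_species=str(cal.get("species", "")),
            days=day_list,
        )
        for ref, cal in calibration.items()
        if ref in models
    }
    missing = set(calibration) - set(models)
    if missing:
        raise ValueError(f"calibration given for classes without models: {sorted(missing)}")

    forced = {int(k): v for k, v in (forced_family or {}).items()}
    ss = np.random.SeedSequence(seed)
    day_seeds = {d: int(s.generate_state(1)[0] % (2**31)) for d, s in
                 zip(day_list, ss.spawn(len(day_list)))}

    slices: Dict[int, DaySlice] = {}
    for d in day_list:
        dataset = adjust_toxicity(sens_set, tafs, class_map, d)
        values = dataset.values()
        if forced.get(d):
            fam_candidates = [forced[d]]
        else:
            fam_candidates = list(families)
        fits, failures = fit_all_families(values, fam_candidates, min_fit_size=min_fit_size)
        if not fits:
            raise SurfaceBuildError(f"day {d}: no candidate family converged ({failures})")
        fit = select_distribution(fits)
        if n_boot > 0:
            pcs = {
                e.protection_pct: e
                for e in bootstrap_ci(
                    values,
                    fit.family,
                    protection_pcts=protection_levels,
                    n_boot=n_boot,
                    seed=day_seeds[d],
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
        slices[d] = DaySlice(day=d, dataset=dataset, fit=fit, pcs=pcs)

    provenance = {
        "seed": int(seed),
        "n_boot": int(n_boot),
        "class_map": dict(class_map),
        "calibration": {k: dict(v) for k, v in calibration.items()},
        "families": list(families),
        "forced_family": forced,
        "config_hash": _config_hash(
            {
                "seed": seed,
                "n_boot": n_boot,
                "class_map": dict(class_map),
                "days": day_list,
                "protection_levels": list(map(float, protection_levels)),
                "families": list(families),
                "forced_family": forced,
            }
        ),
    }
    return TRSSurface(
        slices=slices,
        protection_levels=tuple(float(p) for p in protection_levels),
        provenance=provenance,
    )


def query_surface(surface: TRSSurface, day: int, mode: str, arg: float) -> float:
    """Query one day-slice: ``mode="paf"`` → affected fraction (%) at a
    concentration; ``mode="pc"`` → protective concentration (µg/L) at a
    protection level."""
    s = surface.slice(day)
    if mode == "paf":
        return fraction_affected(s.fit, arg)
    if mode == "pc":
        return protective_concentration(s.fit, arg)
    raise ValueError(f"unknown query mode {mode!r}; expected 'paf' or 'pc'")


def first_day_below(
    surface: TRSSurface, protection_pct: float, threshold: float
) -> Optional[int]:
    """Smallest day whose PC point estimate falls below a threshold."""
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    level = float(protection_pct)
    for d in surface.days:
        if surface.slices[d].pcs[level].point < threshold:
            return d
    return None


def export_trs_table(surface: TRSSurface, destination) -> pd.DataFrame:
    """Write the per-day PC table (full precision plus 2-significant-figure
    display columns) to CSV; returns the frame."""
    df = surface.to_frame()
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(repr)
    out.to_csv(destination, index=False)
    return df


def plot_surface(surface: TRSSurface, destination, cmap: str = "viridis") -> None:
    """Basic 3-D surface plot: ln concentration × affected fraction × day."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = surface.days
    fracs = np.linspace(0.5, 99.5, 60)
    conc = np.empty((len(days), fracs.size))
    for i, d in enumerate(days):
        dist = surface.slices[d].fit.dist
        conc[i] = np.log10(dist.ppf(fracs / 100.0))
    D, F = np.meshgrid(days, fracs, indexing="ij")
    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(111, projection="3d")
    ax.plot_surface(D, conc, F, cmap=cmap, linewidth=0)
    ax.set_xlabel("exposure duration (days)")
    ax.set_ylabel("log10 concentration (µg/L)")
    ax.set_zlabel("affected fraction (%)")
    fig.savefig(destination, dpi=120)
    plt.close(fig)
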