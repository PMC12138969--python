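"""Synthetic bioassay data with known ground truth.

Two generators make every other module testable without any external
download:

* :func:`generate_time_series` draws duration–effect-concentration
  pairs from the power-law model ``EC = exp(alpha + beta ln d + e)``
  with ln-scale Gaussian noise — the shape of reference-species
  time-series bioassay tables.
* :func:`generate_community` draws a community acute toxicity set from
  a log-normal species sensitivity distribution, assigns taxonomic
  classes, and returns the ground truth for recovery tests.

Defaults emulate the imidacloprid study regime this toolkit was built
around: a 32-species arthropod acute set spanning roughly four orders
of magnitude, three reference organisms (a daphnid, a mayfly, and an
amphipod) whose time-response slopes span −0.7 to −3.9, and standard
acute test windows of 2 days (Branchiopoda) or 4 days (Insecta,
Malacostraca).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .records import ToxicityRecord
from .timetox import BioassayPoint

__all__ = [
    "CommunitySpec",
    "ReferenceSeriesSpec",
    "generate_time_series",
    "generate_community",
    "default_community_spec",
    "default_reference_specs",
    "write_fixture_suite",
    "ACUTE_WINDOW_DAYS",
]

#: Standard acute test window per taxonomic class (days).
ACUTE_WINDOW_DAYS: Dict[str, float] = {
    "Branchiopoda": 2.0,  # 48-h daphnid immobilization test
    "Insecta": 4.0,  # 96-h insect acute test
    "Malacostraca": 4.0,  # 96-h amphipod acute test
}

#: Reference time-response slopes used as the default synthetic regime:
#: a fast-accumulating daphnid, an intermediate mayfly, and a slow
#: amphipod.
DEFAULT_CLASS_SLOPES: Dict[str, float] = {
    "Branchiopoda": -3.892,
    "Insecta": -1.827,
    "Malacostraca": -0.737,
}


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth parameters for a synthetic community acute set."""

    n_species: int = 32
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "Insecta": 0.5,
            "Malacostraca": 0.3,
            "Branchiopoda": 0.2,
        }
    )
    ssd_location: float = math.log(100.0)  # ln µg/L community median
    ssd_scale: float = 2.3  # ln-scale spread (~4 orders of magnitude)
    class_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SLOPES)
    )
    noise_sd_log: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 8:
            raise ValueError(f"n_species must be >= 8, got {self.n_species}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        missing = set(self.class_mix) - set(self.class_slopes)
        if missing:
            raise ValueError(
                f"classes in class_mix lack slopes in class_slopes: {sorted(missing)}"
            )
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")


@dataclass(frozen=True)
class ReferenceSeriesSpec:
    """Parameters for one reference species' synthetic time series."""

    species: str
    taxon_class: str
    alpha: float  # ln-scale intercept
    beta: float  # slope
    durations: Tuple[float, ...]
    noise_sd_log: float = 0.15


def generate_time_series(
    alpha: float,
    beta: float,
    durations: Sequence[float],
    noise_sd_log: float = 0.15,
    seed: int = 0,
    endpoint: str = "LC50",
) -> List[BioassayPoint]:
    """Draw a reference time series from the log–log power-law model."""
    durations = [float(d) for d in durations]
    if len(durations) < 5:
        raise ValueError(f"need at least 5 durations, got {len(durations)}")
    if any(d <= 0 for d in durations):
        raise ValueError("durations must be > 0")
    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = rng.normal(0.0, noise_sd_log, size=len(durations)) if noise_sd_log > 0 \
        else np.zeros(len(durations))
    return [
        BioassayPoint(
            duration=d,
            effect_concentration=float(math.exp(alpha + beta * math.log(d) + e)),
            endpoint=endpoint,
            source_id="synthetic",
        )
        for d, e in zip(durations, noise)
    ]


def _largest_remainder_counts(n: int, mix: Mapping[str, float]) -> Dict[str, int]:
    classes = list(mix)
    raw = {c: n * mix[c] for c in classes}
    counts = {c: int(math.floor(raw[c])) for c in classes}
    short = n - sum(counts.values())
    # distribute the remainder to the largest fractional parts, stable order
    order = sorted(classes, key=lambda c: (-(raw[c] - counts[c]), classes.index(c)))
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_community(
    spec: CommunitySpec,
) -> Tuple[List[ToxicityRecord], Dict]:
    """Draw a synthetic acute community toxicity set with ground truth.

    Species acute effect concentrations are log-normal
    (``ln EC ~ Normal(ssd_location, ssd_scale)``) with optional extra
    ln-scale measurement noise; classes are allocated by
    largest-remainder rounding of ``class_mix``; durations are the
    standard acute windows per class. Returns ``(records, truth)``
    where ``truth`` carries the per-species latent values and the class
    slopes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    counts = _largest_remainder_counts(spec.n_species, spec.class_mix)
    records: List[ToxicityRecord] = []
    truth_values: Dict[str, float] = {}
    idx = 0
    for taxon_class in spec.class_mix:
        window = ACUTE_WINDOW_DAYS.get(taxon_class, 4.0)
        for _ in range(counts[taxon_class]):
            idx += 1
            name = f"{taxon_class.lower()} sp{idx:02d}"
            latent = math.exp(
                spec.ssd_location + spec.ssd_scale * rng.standard_normal()
            )
            observed = latent * (
                math.exp(spec.noise_sd_log * rng.standard_normal())
                if spec.noise_sd_log > 0
                else 1.0
            )
            truth_values[name] = latent
            records.append(
                ToxicityRecord(
                    species_name=name,
                    taxon_class=taxon_class,
                    phylum="Arthropoda",
                    medium="freshwater",
                    endpoint="LC50",
                    effect_type="acute",
                    concentration=observed,
                    duration=window,
                    purity_pct=99.0,
                    quality_pct=90.0,
                    source_id="synthetic",
                )
            )
    truth = {
        "species_values": truth_values,
        "class_slopes": dict(spec.class_slopes),
        "ssd_location": spec.ssd_location,
        "ssd_scale": spec.ssd_scale,
        "class_counts": counts,
    }
    return records, truth


def default_community_spec(seed: int = 0, **overrides) -> CommunitySpec:
    """The study-regime community: 32 arthropod species across three classes."""
    kwargs = dict(seed=seed)
    kwargs.update(overrides)
    return CommunitySpec(**kwargs)


def default_reference_specs(noise_sd_log: float = 0.15) -> List[ReferenceSeriesSpec]:
    """Three reference organisms spanning the observed slope range.

    The daphnid series stays within its short observed window (max ~9
    days); the mayfly and amphipod series span 2–28 days, matching the
    windows of standard time-series acute bioassays.
    """
    return [
        ReferenceSeriesSpec(
            species="daphnid ref",
            taxon_class="Branchiopoda",
            alpha=18.92,
            beta=-3.892,
            durations=(1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 9.0),
            noise_sd_log=noise_sd_log,
        ),
        ReferenceSeriesSpec(
            species="mayfly ref",
            taxon_class="Insecta",
            alpha=4.646,
            beta=-1.827,
            durations=(2.0, 4.0, 7.0, 10.0, 14.0, 21.0, 28.0),
            noise_sd_log=noise_sd_log,
        ),
        ReferenceSeriesSpec(
            species="amphipod ref",
            taxon_class="Malacostraca",
            alpha=6.881,
            beta=-0.737,
            durations=(2.0, 4.0, 7.0, 10.0, 14.0, 21.0, 28.0),
            noise_sd_log=noise_sd_log,
        ),
    ]


def write_fixture_suite(directory, seed: int = 0, noise_sd_log: float = 0.15) -> dict:
    """Write a self-contained CSV fixture suite plus a run config.

    Emits ``toxicity.csv`` (community acute set in the canonical
    schema), ``timeseries.csv`` (three reference series),
    ``acr_table.csv`` (per-class literature-style ACRs), and
    ``config.yaml`` wiring them together. Returns the paths.
    """
    import pandas as pd
    import yaml
    from pathlib import Path

    from .records import write_toxicity_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    records, truth = generate_community(
        default_community_spec(seed=child_seeds[0], noise_sd_log=noise_sd_log)
    )
    tox_path = directory / "toxicity.csv"
    write_toxicity_table(records, tox_path)

    rows = []
    calibration = {}
    for spec, s in zip(default_reference_specs(noise_sd_log), child_seeds[1:]):
        series = generate_time_series(
            spec.alpha, spec.beta, spec.durations, spec.noise_sd_log, seed=s
        )
        window = ACUTE_WINDOW_DAYS[spec.taxon_class]
        nearest = min(series, key=lambda p: abs(p.duration - window))
        calibration[spec.taxon_class] = {
            "species": spec.species,
            "ec_measured": float(nearest.effect_concentration),
            "measured_day": float(nearest.duration),
        }
        for p in series:
            rows.append(
                {
                    "species": spec.species,
                    "class": spec.taxon_class,
                    "duration_days": repr(p.duration),
                    "endpoint": p.endpoint,
                    "effect_concentration_ugL": repr(p.effect_concentration),
                    "source_id": p.source_id,
                }
            )
    ts_path = directory / "timeseries.csv"
    pd.DataFrame(rows).to_csv(ts_path, index=False)

    acr_path = directory / "acr_table.csv"
    pd.DataFrame(
        [
            {"taxon_class": "Insecta", "acr": 22.6, "acr_min": 2.9,
             "acr_max": 150.24, "source_id": "synthetic"},
            {"taxon_class": "Malacostraca", "acr": 12.0, "acr_min": 10.0,
             "acr_max": 35.0, "source_id": "synthetic"},
            {"taxon_class": "Branchiopoda", "acr": 15.0, "acr_min": 10.0,
             "acr_max": 40.0, "source_id": "synthetic"},
        ]
    ).to_csv(acr_path, index=False)

    cfg = {
        "toxicity_csv": "toxicity.csv",
        "timeseries_csv": "timeseries.csv",
        "acr_table_csv": "acr_table.csv",
        "class_map": {
            "Insecta": "Insecta",
            "Malacostraca": "Malacostraca",
            "Branchiopoda": "Branchiopoda",
        },
        "calibration": calibration,
        "acr_scenarios": [10.0, 50.0, 100.0],
        "use_acr_table": True,
        "n_boot_pc": 0,
        "seed": int(seed),
        "output_dir": "output",
    }
    cfg_path = directory / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {
        "toxicity_csv": tox_path,
        "timeseries_csv": ts_path,
        "acr_table_csv": acr_path,
        "config": cfg_path,
        "truth": truth,
    }
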