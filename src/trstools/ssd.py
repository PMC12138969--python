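"""Species sensitivity distribution fitting, selection, and quantiles.

A species sensitivity distribution (SSD) is a parametric distribution
fitted by maximum likelihood to per-species toxicity values (µg/L). The
protective concentration PCx — the concentration protecting x% of
species — is its (100 − x)th percentile, and the potentially affected
fraction (PAF) at a concentration is the CDF there, in percent.

Candidate families are compared by AICc; confidence intervals for
protective concentrations come from a parametric bootstrap (draw a
synthetic community of the same size from the fitted distribution,
refit, recompute the quantile; repeat).
"""

from __future__ import annotations

import json
import math
import numbers
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .distributions import (
    FAMILIES,
    FAMILY_ORDER,
    DegenerateSampleError,
    FitConvergenceError,
    get_family,
)

__all__ = [
    "SSDFit",
    "PCEstimate",
    "SSDFitter",
    "fit_distribution",
    "fit_all_families",
    "select_distribution",
    "protective_concentration",
    "fraction_affected",
    "bootstrap_ci",
    "BootstrapInstabilityError",
]

DEFAULT_MIN_FIT_SIZE = 8
DEFAULT_PROTECTION_LEVELS = (99.0, 95.0, 90.0, 80.0)


class BootstrapInstabilityError(RuntimeError):
    """Too many bootstrap replicates failed to converge."""


@dataclass(frozen=True)
class SSDFit:
    """A maximum-likelihood SSD fit for one family.

    ``params`` follows the family's documented parameterization (see
    :mod:`trstools.distributions`). ``gof`` carries the Anderson–Darling
    and Kolmogorov–Smirnov statistics against the fitted CDF.
    """

    family: str
    params: Tuple[float, ...]
    n: int
    loglik: float
    aicc: float
    gof: Dict[str, float] = field(default_factory=dict)

    @property
    def dist(self):
        """Frozen scipy distribution on the raw concentration scale."""
        return get_family(self.family).freeze(self.params)

    def to_json(self, **extra) -> str:
        rec = {
            "family": self.family,
            "params": dict(zip(get_family(self.family).param_names, self.params)),
            "n": self.n,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "gof": dict(self.gof),
        }
        rec.update(extra)
        return json.dumps(rec, sort_keys=True)


@dataclass(frozen=True)
class PCEstimate:
    """A protective concentration with a percentile-bootstrap interval."""

    protection_pct: float
    point: float
    ci_lower: float
    ci_upper: float
    n_boot: int


def _gof_statistics(values: np.ndarray, frozen) -> Dict[str, float]:
    x = np.sort(values)
    n = x.size
    cdf = np.clip(frozen.cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1])))
    ks = stats.kstest(values, frozen.cdf).statistic
    return {"anderson_darling": float(a2), "kolmogorov_smirnov": float(ks)}


def fit_distribution(
    values: Sequence[float],
    family: str,
    min_fit_size: int = DEFAULT_MIN_FIT_SIZE,
) -> SSDFit:
    """Fit one family by maximum likelihood.

    Raises
    ------
    ValueError : fewer than ``min_fit_size`` values, or non-positive values.
    DegenerateSampleError : all values identical.
    FitConvergenceError : the optimizer failed for this family.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < min_fit_size:
        raise ValueError(
            f"need at least {min_fit_size} species values to fit an SSD, got {values.size}"
        )
    fam = get_family(family)
    try:
        params = fam.fit(values)
    except DegenerateSampleError:
        raise
    except ValueError:
        raise
    except Exception as exc:  # scipy optimizer failures
        raise FitConvergenceError(f"{family} fit did not converge: {exc}") from exc
    frozen = fam.freeze(params)
    loglik = float(np.sum(frozen.logpdf(values)))
    if not np.isfinite(loglik):
        raise FitConvergenceError(f"{family} fit produced non-finite log-likelihood")
    k = len(params)
    n = values.size
    aicc = -2.0 * loglik + 2.0 * k
    if n - k - 1 > 0:
        aicc += 2.0 * k * (k + 1) / (n - k - 1)
    else:
        # correction denominator vanishes below n = k + 2; such fits are
        # still usable for quantiles but never win AICc selection
        aicc = math.inf
    return SSDFit(
        family=family,
        params=tuple(float(p) for p in params),
        n=int(n),
        loglik=loglik,
        aicc=float(aicc),
        gof=_gof_statistics(values, frozen),
    )


def fit_all_families(
    values: Sequence[float],
    families: Sequence[str] = FAMILY_ORDER,
    min_fit_size: int = DEFAULT_MIN_FIT_SIZE,
) -> Tuple[List[SSDFit], Dict[str, str]]:
    """Fit every requested family, collecting per-family failures.

    Returns (converged fits, {family: failure reason}).
    """
    fits: List[SSDFit] = []
    failures: Dict[str, str] = {}
    for fam in families:
        try:
            fits.append(fit_distribution(values, fam, min_fit_size=min_fit_size))
        except (FitConvergenceError, DegenerateSampleError, ValueError) as exc:
            failures[fam] = str(exc)
    return fits, failures


def select_distribution(fits: Sequence[SSDFit]) -> SSDFit:
    """Return the fit with minimum AICc; ties broken by fixed family order."""
    if not fits:
        raise ValueError("no converged fits to select from")
    order = {name: i for i, name in enumerate(FAMILY_ORDER)}
    return min(fits, key=lambda f: (f.aicc, order.get(f.family, len(order))))


def protective_concentration(fit: SSDFit, protection_pct: float) -> float:
    """PCx: the (100 − x)th percentile of the fitted distribution (µg/L)."""
    if not (0.0 < protection_pct < 100.0):
        raise ValueError(f"protection_pct must be in (0, 100), got {protection_pct}")
    return float(fit.dist.ppf((100.0 - protection_pct) / 100.0))


def fraction_affected(fit: SSDFit, concentration: float) -> float:
    """Potentially affected fraction at a concentration, in percent."""
    if not isinstance(concentration, numbers.Real) or concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration!r}")
    return float(100.0 * fit.dist.cdf(concentration))


def bootstrap_ci(
    values: Sequence[float],
    family: str,
    protection_pcts: Sequence[float] = DEFAULT_PROTECTION_LEVELS,
    n_boot: int = 10_000,
    seed: int = 0,
    pc_point: str = "fit",
    max_failure_fraction: float = 0.20,
    min_fit_size: int = DEFAULT_MIN_FIT_SIZE,
) -> List[PCEstimate]:
    """Parametric-bootstrap confidence intervals for protective concentrations.

    Each replicate draws ``n`` synthetic species values from the
    original-data fit, refits the same family, and recomputes each PC;
    the interval is the 2.5/97.5 percentile of the replicate PCs. The
    point estimate comes from the original-data fit (``pc_point="fit"``,
    the default) or the replicate median (``pc_point="bootstrap_median"``).

    Replicate RNG streams are split from ``seed`` by replicate index, so
    results do not depend on execution order.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if pc_point not in ("fit", "bootstrap_median"):
        raise ValueError(f"unknown pc_point mode {pc_point!r}")
    base_fit = fit_distribution(values, family, min_fit_size=min_fit_size)
    n = base_fit.n
    frozen = base_fit.dist
    fam = get_family(family)
    qs = [(100.0 - p) / 100.0 for p in protection_pcts]
    for p in protection_pcts:
        if not (0.0 < p < 100.0):
            raise ValueError(f"protection_pct must be in (0, 100), got {p}")

    children = np.random.SeedSequence(seed).spawn(n_boot)
    reps = np.full((n_boot, len(qs)), np.nan)
    failures = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sample = frozen.rvs(size=n, random_state=rng)
        try:
            params = fam.fit(sample)
            reps[i] = fam.freeze(params).ppf(qs)
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_boot:
        raise BootstrapInstabilityError(
            f"{failures}/{n_boot} bootstrap replicates failed to converge "
            f"for family {family!r} (n={n})"
        )
    ok = reps[~np.isnan(reps).any(axis=1)]
    lo = np.percentile(ok, 2.5, axis=0)
    hi = np.percentile(ok, 97.5, axis=0)
    med = np.percentile(ok, 50.0, axis=0)
    out = []
    for j, p in enumerate(protection_pcts):
        point = (
            protective_concentration(base_fit, p)
            if pc_point == "fit"
            else float(med[j])
        )
        out.append(
            PCEstimate(
                protection_pct=float(p),
                point=point,
                ci_lower=float(lo[j]),
                ci_upper=float(hi[j]),
                n_boot=int(n_boot),
            )
        )
    return out


class SSDFitter(BaseEstimator):
    """Species sensitivity distribution estimator.

    Parameters
    ----------
    family : one of the five family names, or ``"auto"`` to fit all
        candidates and keep the minimum-AICc fit.
    families : candidate set used when ``family="auto"``.
    min_fit_size : smallest acceptable number of species values.

    Attributes (after ``fit``)
    --------------------------
    fit_ : SSDFit — the selected fit.
    candidates_ : list[SSDFit] — every converged candidate.
    failures_ : dict — per-family failure reasons.
    family_ : str — selected family name.
    """

    def __init__(
        self,
        family: str = "auto",
        families: Sequence[str] = FAMILY_ORDER,
        min_fit_size: int = DEFAULT_MIN_FIT_SIZE,
    ):
        self.family = family
        self.families = families
        self.min_fit_size = min_fit_size

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of concentrations")
            X = X[:, 0]
        if self.family == "auto":
            fits, failures = fit_all_families(
                X, self.families, min_fit_size=self.min_fit_size
            )
            if not fits:
                raise FitConvergenceError(f"no family converged: {failures}")
            self.fit_ = select_distribution(fits)
            self.candidates_ = fits
            self.failures_ = failures
        else:
            self.fit_ = fit_distribution(X, self.family, min_fit_size=self.min_fit_size)
            self.candidates_ = [self.fit_]
            self.failures_ = {}
        self.family_ = self.fit_.family
        self.params_ = self.fit_.params
        return self

    def protective_concentration(self, protection_pct: float) -> float:
        self._check_fitted()
        return protective_concentration(self.fit_, protection_pct)

    def fraction_affected(self, concentration: float) -> float:
        self._check_fitted()
        return fraction_affected(self.fit_, concentration)

    def _check_fitted(self):
        if not hasattr(self, "fit_"):
            raise RuntimeError("SSDFitter is not fitted; call fit() first")
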