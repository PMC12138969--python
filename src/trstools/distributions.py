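"""Candidate distribution families for species sensitivity distributions.

Five unimodal families are supported, the set conventionally used for
water-quality guideline derivation: gamma, log-Gumbel (equivalently the
inverse Weibull / Fréchet distribution on the raw concentration scale),
log-logistic, log-normal, and Weibull.

Parameterization conventions
----------------------------
The three ``log_*`` families are location–scale families applied to the
natural log of concentration:

* ``log_normal``:   Normal(loc, scale) on ln(x); ``loc`` is the ln-scale
  mean, ``scale`` the ln-scale standard deviation.
* ``log_logistic``: Logistic(loc, scale) on ln(x).
* ``log_gumbel``:   Gumbel (type-I extreme value, maximum convention) on
  ln(x); on the raw scale this is the inverse Weibull with shape
  ``1/scale`` and scale ``exp(loc)``.

``gamma`` (shape, scale) and ``weibull`` (shape, scale) act on the raw
concentration scale with the location pinned at zero.

All families expose maximum-likelihood ``fit`` (closed form for
log-normal; numerical with deterministic moment-based starting values
otherwise) and a frozen scipy distribution on the raw concentration
scale for cdf/ppf/rvs/logpdf, so protective concentrations and affected
fractions are plain quantile/CDF evaluations regardless of family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "FAMILY_ORDER",
    "DegenerateSampleError",
    "FitConvergenceError",
    "Family",
    "get_family",
]

# Fixed preference order, used for AICc tie-breaking during selection.
FAMILY_ORDER: Tuple[str, ...] = (
    "log_normal",
    "log_logistic",
    "log_gumbel",
    "gamma",
    "weibull",
)

_EULER_GAMMA = 0.5772156649015329


class DegenerateSampleError(ValueError):
    """All sample values identical: no spread to fit a distribution to."""


class FitConvergenceError(RuntimeError):
    """Maximum-likelihood optimization failed for a family."""


@dataclass(frozen=True)
class Family:
    """One candidate SSD family.

    Attributes
    ----------
    name : canonical family name.
    param_names : names of the fitted parameter vector, in order.
    fit : maps positive sample values to the MLE parameter tuple.
    freeze : maps a parameter tuple to a frozen scipy distribution on
        the raw concentration scale.
    """

    name: str
    param_names: Tuple[str, ...]
    fit: Callable[[np.ndarray], Tuple[float, ...]]
    freeze: Callable[[Tuple[float, ...]], stats._distn_infrastructure.rv_frozen]


def _validate_sample(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("sample values must be finite and > 0")
    if np.ptp(values) == 0:
        raise DegenerateSampleError(
            "all sample values are identical; cannot fit a distribution"
        )
    return values


def _fit_log_normal(values: np.ndarray) -> Tuple[float, float]:
    # Closed-form MLE: ln-scale mean and RMS deviation (1/n denominator).
    logs = np.log(_validate_sample(values))
    loc = float(np.mean(logs))
    scale = float(np.sqrt(np.mean((logs - loc) ** 2)))
    return loc, scale


def _fit_log_logistic(values: np.ndarray) -> Tuple[float, float]:
    logs = np.log(_validate_sample(values))
    loc0 = float(np.mean(logs))
    scale0 = float(np.std(logs) * math.sqrt(3.0) / math.pi)
    loc, scale = stats.logistic.fit(logs, loc=loc0, scale=max(scale0, 1e-8))
    return float(loc), float(scale)


def _fit_log_gumbel(values: np.ndarray) -> Tuple[float, float]:
    logs = np.log(_validate_sample(values))
    scale0 = float(np.std(logs) * math.sqrt(6.0) / math.pi)
    loc0 = float(np.mean(logs) - _EULER_GAMMA * max(scale0, 1e-8))
    loc, scale = stats.gumbel_r.fit(logs, loc=loc0, scale=max(scale0, 1e-8))
    return float(loc), float(scale)


def _fit_gamma(values: np.ndarray) -> Tuple[float, float]:
    # normalize by the geometric mean before optimizing so the fit is
    # scale-equivariant to high precision (shape is scale-free)
    values = _validate_sample(values)
    s0 = float(np.exp(np.mean(np.log(values))))
    shape, _, scale = stats.gamma.fit(values / s0, floc=0)
    return float(shape), float(scale * s0)


def _fit_weibull(values: np.ndarray) -> Tuple[float, float]:
    values = _validate_sample(values)
    s0 = float(np.exp(np.mean(np.log(values))))
    shape, _, scale = stats.weibull_min.fit(values / s0, floc=0)
    return float(shape), float(scale * s0)


FAMILIES: Dict[str, Family] = {
    "log_normal": Family(
        name="log_normal",
        param_names=("loc", "scale"),
        fit=_fit_log_normal,
        freeze=lambda p: stats.lognorm(s=p[1], scale=math.exp(p[0])),
    ),
    "log_logistic": Family(
        name="log_logistic",
        param_names=("loc", "scale"),
        fit=_fit_log_logistic,
        freeze=lambda p: stats.fisk(c=1.0 / p[1], scale=math.exp(p[0])),
    ),
    "log_gumbel": Family(
        name="log_gumbel",
        param_names=("loc", "scale"),
        fit=_fit_log_gumbel,
        freeze=lambda p: stats.invweibull(c=1.0 / p[1], scale=math.exp(p[0])),
    ),
    "gamma": Family(
        name="gamma",
        param_names=("shape", "scale"),
        fit=_fit_gamma,
        freeze=lambda p: stats.gamma(a=p[0], scale=p[1]),
    ),
    "weibull": Family(
        name="weibull",
        param_names=("shape", "scale"),
        fit=_fit_weibull,
        freeze=lambda p: stats.weibull_min(c=p[0], scale=p[1]),
    ),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown distribution family {name!r}; expected one of {sorted(FAMILIES)}"
        ) from None
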