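"""Time–toxicity regression for reference species.

For a toxicant with time-cumulative action, the effect concentration
(e.g. an LC50) declines with exposure duration approximately as a power
law. The model fitted here is a Gaussian generalized linear model with
identity link on the natural logs of both variables,

    ln EC = alpha + beta * ln ED + eps,

where EC is the effect concentration (µg/L), ED the exposure duration
(days), alpha the ln-scale intercept, beta the (negative) slope, and eps
Gaussian residual error. On the raw scale the point prediction is
``EC(d) = exp(alpha) * d**beta``.

Diagnostics reported alongside the coefficients: D² (explained deviance,
equal to R² for this model), leave-one-out cross-validated MSE on the ln
scale, and Cook's distance-based influential-point screening with a
single re-fit pass. An inflection day bounds the useful prediction
window: the first day at which the decline between successive modelled
daily estimates falls below a threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BioassayPoint",
    "TimeResponseRegressor",
    "ExtrapolationWarning",
    "fit_time_response",
    "predict_ec",
    "inflection_day",
    "read_time_series",
]

MIN_POINTS = 5
DEFAULT_EXTRAPOLATION_GUARD = 100


class ExtrapolationWarning(UserWarning):
    """Prediction requested beyond the supported exposure window."""


@dataclass(frozen=True)
class BioassayPoint:
    """One duration–effect-concentration pair from a time-series bioassay."""

    duration: float  # days
    effect_concentration: float  # µg/L
    endpoint: str = "LC50"
    source_id: str = ""

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not self.effect_concentration > 0:
            raise ValueError(
                f"effect_concentration must be > 0, got {self.effect_concentration}"
            )


class TimeResponseRegressor(BaseEstimator, RegressorMixin):
    """Log–log time-toxicity regression (Gaussian GLM, identity link).

    Parameters
    ----------
    cooks_threshold : Cook's distance above which a point is flagged as
        influential and removed in a single re-fit pass. ``None``
        disables removal.
    inflection_threshold : successive-day relative decline below which
        toxicity change is considered negligible.
    inflection_horizon : last day scanned for the inflection point.
    min_points : minimum usable observations after removals.

    Attributes (after ``fit``)
    --------------------------
    intercept_, slope_ : ln-scale coefficients (alpha, beta).
    se_intercept_, se_slope_ : coefficient standard errors.
    cov_params_ : 2×2 coefficient covariance matrix.
    residual_variance_ : ln-scale residual variance (deviance / df).
    dsquared_ : explained deviance, in [0, 1].
    loocv_mse_ : leave-one-out mean squared prediction error (ln scale).
    n_points_ : observations used in the final fit.
    removed_points_ : indices (into the input) removed as influential.
    fit_window_max_day_ : largest observed duration.
    inflection_day_ : first day with negligible successive decline.
    """

    def __init__(
        self,
        cooks_threshold: Optional[float] = 1.0,
        inflection_threshold: float = 0.05,
        inflection_horizon: int = 365,
        min_points: int = MIN_POINTS,
    ):
        self.cooks_threshold = cooks_threshold
        self.inflection_threshold = inflection_threshold
        self.inflection_horizon = inflection_horizon
        self.min_points = min_points

    # -- fitting ------------------------------------------------------

    def fit(self, X, y):
        """Fit on durations ``X`` (days; shape (n,) or (n, 1)) and effect
        concentrations ``y`` (µg/L)."""
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            if d.shape[1] != 1:
                raise ValueError("X must be a single column of durations")
            d = d[:, 0]
        ec = np.asarray(y, dtype=float).ravel()
        if d.shape != ec.shape:
            raise ValueError("X and y must have the same length")
        if np.any(d <= 0) or np.any(ec <= 0):
            raise ValueError("durations and effect concentrations must be > 0")
        if d.size < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} points, got {d.size}"
            )
        if np.ptp(d) == 0:
            raise ValueError("all durations equal: regression is rank-deficient")

        keep = np.arange(d.size)
        res = self._glm_fit(np.log(d[keep]), np.log(ec[keep]))
        removed: List[int] = []
        # Cook's distance degenerates on an (almost) exact fit; skip the
        # influence pass when there is effectively no residual deviance.
        if self.cooks_threshold is not None and res.deviance > 1e-10 * max(
            res.null_deviance, 1.0
        ):
            cooks = np.nan_to_num(
                np.asarray(res.get_influence().cooks_distance[0]), nan=0.0
            )
            flagged = keep[cooks > self.cooks_threshold]
            if flagged.size:
                keep = np.setdiff1d(keep, flagged)
                if keep.size < self.min_points:
                    raise ValueError(
                        f"influential-point removal leaves {keep.size} points; "
                        f"need at least {self.min_points}"
                    )
                if np.ptp(d[keep]) == 0:
                    raise ValueError("all remaining durations equal after removals")
                removed = [int(i) for i in flagged]
                res = self._glm_fit(np.log(d[keep]), np.log(ec[keep]))

        params = np.asarray(res.params, dtype=float)
        self.intercept_ = float(params[0])
        self.slope_ = float(params[1])
        bse = np.asarray(res.bse, dtype=float)
        self.se_intercept_ = float(bse[0])
        self.se_slope_ = float(bse[1])
        self.tvalues_ = tuple(float(t) for t in np.asarray(res.tvalues))
        self.pvalues_ = tuple(float(p) for p in np.asarray(res.pvalues))
        self.cov_params_ = np.asarray(res.cov_params(), dtype=float)
        n = keep.size
        self.n_points_ = int(n)
        self.removed_points_ = removed
        dof = max(n - 2, 1)
        self.residual_variance_ = float(res.deviance / dof)
        self.dsquared_ = float(1.0 - res.deviance / res.null_deviance)
        self.loocv_mse_ = self._loocv_mse(np.log(d[keep]), np.log(ec[keep]))
        self.fit_window_max_day_ = float(np.max(d[keep]))
        self._log_d = np.log(d[keep])
        self._log_ec = np.log(ec[keep])
        if self.slope_ < 0:
            self.inflection_day_ = inflection_day(
                self,
                threshold=self.inflection_threshold,
                horizon=self.inflection_horizon,
            )
        else:
            warnings.warn(
                f"non-negative slope {self.slope_:.4g}: toxicity does not "
                "accumulate with duration; inflection day undefined",
                UserWarning,
                stacklevel=2,
            )
            self.inflection_day_ = None
        return self

    @staticmethod
    def _glm_fit(log_d: np.ndarray, log_ec: np.ndarray):
        exog = sm.add_constant(log_d)
        return sm.GLM(log_ec, exog, family=sm.families.Gaussian()).fit()

    @staticmethod
    def _loocv_mse(log_d: np.ndarray, log_ec: np.ndarray) -> float:
        errs = []
        n = log_d.size
        for i in range(n):
            mask = np.arange(n) != i
            exog = sm.add_constant(log_d[mask])
            res = sm.OLS(log_ec[mask], exog).fit()
            pred = res.params[0] + res.params[1] * log_d[i]
            errs.append((log_ec[i] - pred) ** 2)
        return float(np.mean(errs))

    @classmethod
    def from_coefficients(
        cls,
        intercept: float,
        slope: float,
        se_intercept: float = 0.0,
        se_slope: float = 0.0,
        cov_params: Optional[np.ndarray] = None,
        fit_window_max_day: float = np.inf,
        **kwargs,
    ) -> "TimeResponseRegressor":
        """Build a fitted model directly from published coefficients."""
        model = cls(**kwargs)
        model.intercept_ = float(intercept)
        model.slope_ = float(slope)
        model.se_intercept_ = float(se_intercept)
        model.se_slope_ = float(se_slope)
        model.cov_params_ = (
            np.asarray(cov_params, dtype=float)
            if cov_params is not None
            else np.diag([se_intercept**2, se_slope**2])
        )
        model.tvalues_ = ()
        model.pvalues_ = ()
        model.residual_variance_ = 0.0
        model.dsquared_ = float("nan")
        model.loocv_mse_ = float("nan")
        model.n_points_ = 0
        model.removed_points_ = []
        model.fit_window_max_day_ = float(fit_window_max_day)
        model.inflection_day_ = (
            inflection_day(model, threshold=model.inflection_threshold,
                           horizon=model.inflection_horizon)
            if model.slope_ < 0
            else None
        )
        return model

    # -- prediction ---------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Point prediction EC(d) = exp(alpha + beta ln d), µg/L."""
        self._check_fitted()
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            d = d[:, 0]
        if np.any(d < 1):
            raise ValueError("prediction days must be >= 1")
        return np.exp(self.intercept_ + self.slope_ * np.log(d))

    def predict_interval(
        self,
        days: Sequence[float],
        n_boot: int = 1000,
        seed: int = 0,
        guard: int = DEFAULT_EXTRAPOLATION_GUARD,
        method: str = "coefficients",
    ) -> pd.DataFrame:
        """Point estimates with 95% parametric-bootstrap intervals.

        ``method="coefficients"`` (default) draws (alpha*, beta*) from
        the estimated Gaussian sampling distribution of the
        coefficients; ``method="residuals"`` resamples ln-scale
        residual noise onto the fitted line (an option for small n).
        Reproducible given ``seed``. Days beyond the inflection day or
        the extrapolation guard carry a warning flag.
        """
        self._check_fitted()
        days_arr = np.asarray(list(days), dtype=float)
        if np.any(days_arr < 1):
            raise ValueError("days must be >= 1")
        if n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {n_boot}")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        logd = np.log(days_arr)
        if method == "coefficients":
            draws = rng.multivariate_normal(
                [self.intercept_, self.slope_], self.cov_params_, size=n_boot,
                method="cholesky" if np.all(np.linalg.eigvalsh(self.cov_params_) > 0)
                else "svd",
            )
        elif method == "residuals":
            if not hasattr(self, "_log_d"):
                raise RuntimeError(
                    "residual resampling requires a model fitted from data"
                )
            yhat = self.intercept_ + self.slope_ * self._log_d
            resid = self._log_ec - yhat
            exog = sm.add_constant(self._log_d)
            draws = np.empty((n_boot, 2))
            for b in range(n_boot):
                ystar = yhat + rng.choice(resid, size=resid.size, replace=True)
                draws[b] = sm.OLS(ystar, exog).fit().params
        else:
            raise ValueError(f"unknown interval method {method!r}")
        preds = np.exp(draws[:, [0]] + draws[:, [1]] * logd[None, :])
        lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
        point = self.predict(days_arr)
        limit = min(
            guard,
            self.inflection_day_ if self.inflection_day_ is not None else guard,
        )
        beyond = days_arr > limit
        if np.any(beyond):
            warnings.warn(
                f"{int(beyond.sum())} requested day(s) exceed the supported "
                f"window (day {limit}); predictions are extrapolations",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return pd.DataFrame(
            {
                "day": days_arr,
                "point": point,
                "ci_lower": lo,
                "ci_upper": hi,
                "extrapolated": beyond,
            }
        )

    def report(self) -> Dict:
        """Coefficient table mirroring the usual regression report."""
        self._check_fitted()
        return {
            "coefficients": {
                "y_intercept": {
                    "estimate": self.intercept_,
                    "std_error": self.se_intercept_,
                },
                "ln_exposure_duration": {
                    "estimate": self.slope_,
                    "std_error": self.se_slope_,
                },
            },
            "t_values": list(self.tvalues_),
            "p_values": list(self.pvalues_),
            "dsquared": self.dsquared_,
            "loocv_mse": self.loocv_mse_,
            "residual_variance": self.residual_variance_,
            "n_points": self.n_points_,
            "removed_points": list(self.removed_points_),
            "inflection_day": self.inflection_day_,
        }

    def to_json(self, **extra) -> str:
        rec = self.report()
        rec.update(extra)
        return json.dumps(rec, sort_keys=True)

    def _check_fitted(self):
        if not hasattr(self, "slope_"):
            raise RuntimeError("TimeResponseRegressor is not fitted")


def fit_time_response(
    series: Sequence[BioassayPoint],
    cooks_threshold: Optional[float] = 1.0,
    **kwargs,
) -> TimeResponseRegressor:
    """Fit the log–log time-toxicity regression to a bioassay series."""
    d = np.array([p.duration for p in series], dtype=float)
    ec = np.array([p.effect_concentration for p in series], dtype=float)
    return TimeResponseRegressor(cooks_threshold=cooks_threshold, **kwargs).fit(d, ec)


def predict_ec(
    model: TimeResponseRegressor,
    days: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-day point estimates and 95% bootstrap intervals (µg/L)."""
    return model.predict_interval(days, n_boot=n_boot, seed=seed)


def inflection_day(
    model: TimeResponseRegressor,
    rule: str = "relative_change",
    threshold: float = 0.05,
    horizon: int = 365,
) -> int:
    """First whole day at which successive daily toxicity change is negligible.

    Under the default ``relative_change`` rule, returns the first day
    ``d <= horizon`` with ``1 - ((d+1)/d)**slope < threshold`` — the
    relative decline between the modelled day-d and day-(d+1) estimates
    drops below the threshold. If the horizon is reached first it is
    returned with a warning.
    """
    if rule != "relative_change":
        raise ValueError(f"unknown inflection rule {rule!r}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    slope = model.slope_
    if slope >= 0:
        raise ValueError("inflection day undefined for non-negative slope")
    for d in range(1, horizon + 1):
        decline = 1.0 - ((d + 1) / d) ** slope
        if decline < threshold:
            return d
    warnings.warn(
        f"relative decline never fell below {threshold} within {horizon} days",
        UserWarning,
        stacklevel=2,
    )
    return horizon


def read_time_series(source) -> Dict[str, Tuple[str, List[BioassayPoint]]]:
    """Read reference time-series CSV.

    Expected columns: species, class, duration_days, endpoint,
    effect_concentration_ugL, source_id. Returns
    ``{species: (taxon_class, [BioassayPoint, ...])}``.
    """
    df = pd.read_csv(source)
    required = {"species", "class", "duration_days", "effect_concentration_ugL"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-series table missing columns: {sorted(missing)}")
    out: Dict[str, Tuple[str, List[BioassayPoint]]] = {}
    for sp, grp in df.groupby("species", sort=False):
        pts = [
            BioassayPoint(
                duration=float(r["duration_days"]),
                effect_concentration=float(r["effect_concentration_ugL"]),
                endpoint=str(r.get("endpoint", "LC50")),
                source_id=str(r.get("source_id", "")),
            )
            for _, r in grp.iterrows()
        ]
        out[str(sp)] = (str(grp["class"].iloc[0]), pts)
    return out
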