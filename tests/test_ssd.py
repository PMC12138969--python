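"""SSD fitting, family selection, protective concentrations, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trstools.distributions import FAMILY_ORDER, DegenerateSampleError
from trstools.ssd import (
    PCEstimate,
    SSDFit,
    SSDFitter,
    bootstrap_ci,
    fit_distribution,
    fit_all_families,
    fraction_affected,
    protective_concentration,
    select_distribution,
)


def _lognormal_sample(rng, n=40, loc=1.0, scale=0.8):
    return np.exp(loc + scale * rng.standard_normal(n))


class TestFitDistribution:
    def test_lognormal_closed_form_tiny_sample(self):
        fit = fit_distribution([math.e, math.e**2, math.e**3], "log_normal",
                               min_fit_size=3)
        assert fit.params[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.params[1] == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)

    def test_lognormal_large_sample_recovery(self, rng):
        x = np.exp(rng.standard_normal(10_000))
        fit = fit_distribution(x, "log_normal")
        assert abs(fit.params[0]) < 0.05
        assert abs(fit.params[1] - 1.0) < 0.05

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            fit_distribution([1.0] * 8, "log_normal")

    def test_minimum_fit_size_enforced(self):
        with pytest.raises(ValueError, match="at least 8"):
            fit_distribution([1.0, 2.0, 3.0], "log_normal")

    @pytest.mark.parametrize("family", FAMILY_ORDER)
    def test_all_families_converge_on_lognormal_like_data(self, family, rng):
        fit = fit_distribution(_lognormal_sample(rng), family)
        assert np.isfinite(fit.loglik)
        assert np.isfinite(fit.aicc)
        assert fit.gof["kolmogorov_smirnov"] >= 0
        assert all(p > 0 for p in fit.params[1:])  # scale/shape positive

    def test_aicc_prefers_true_family(self, rng):
        # log-normal data of decent size: the log-normal fit should win
        x = _lognormal_sample(rng, n=500)
        fits, failures = fit_all_families(x)
        assert not failures
        assert select_distribution(fits).family == "log_normal"


class TestSelection:
    def _fit(self, family, aicc):
        return SSDFit(family=family, params=(1.0, 1.0), n=10, loglik=0.0, aicc=aicc)

    def test_single_candidate(self):
        f = self._fit("gamma", 5.0)
        assert select_distribution([f]) is f

    def test_strict_minimum(self):
        a, b = self._fit("weibull", 100.0), self._fit("gamma", 101.0)
        assert select_distribution([b, a]) is a

    def test_tie_broken_by_family_order(self):
        fits = [self._fit(f, 50.0) for f in ("gamma", "log_logistic", "log_normal")]
        assert select_distribution(fits).family == "log_normal"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_distribution([])


class TestProtectiveConcentration:
    def test_median_is_exp_location(self):
        fit = SSDFit("log_normal", (2.0, 0.7), 10, 0.0, 0.0)
        assert protective_concentration(fit, 50.0) == pytest.approx(math.e**2)

    def test_closed_form_pc95(self):
        # normal quantile z_0.05 = -1.6449: exp(ln100 - 1.6449 ln10)
        fit = SSDFit("log_normal", (math.log(100.0), math.log(10.0)), 10, 0.0, 0.0)
        expected = math.exp(math.log(100.0) - 1.6448536269514722 * math.log(10.0))
        assert protective_concentration(fit, 95.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.2654, abs=1e-4)

    def test_monotone_in_protection_level(self):
        fit = SSDFit("log_normal", (1.0, 1.3), 10, 0.0, 0.0)
        assert protective_concentration(fit, 99.0) < protective_concentration(fit, 80.0)

    def test_out_of_range_level(self):
        fit = SSDFit("log_normal", (1.0, 1.0), 10, 0.0, 0.0)
        for bad in (0.0, 100.0, -5.0):
            with pytest.raises(ValueError):
                protective_concentration(fit, bad)


@st.composite
def _family_and_params(draw):
    family = draw(st.sampled_from(FAMILY_ORDER))
    if family in ("log_normal", "log_logistic", "log_gumbel"):
        params = (
            draw(st.floats(min_value=-3, max_value=8)),
            draw(st.floats(min_value=0.05, max_value=3.0)),
        )
    else:
        params = (
            draw(st.floats(min_value=0.3, max_value=8.0)),  # shape
            draw(st.floats(min_value=1e-3, max_value=1e4)),  # scale
        )
    return family, params


class TestFractionAffected:
    def test_cdf_at_median_is_fifty(self):
        fit = SSDFit("log_normal", (0.5, 1.1), 10, 0.0, 0.0)
        med = protective_concentration(fit, 50.0)
        assert fraction_affected(fit, med) == pytest.approx(50.0, abs=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(_family_and_params(), st.floats(min_value=0.5, max_value=99.5))
    def test_pc_paf_round_trip_all_families(self, fp, protection):
        family, params = fp
        fit = SSDFit(family, params, 10, 0.0, 0.0)
        pc = protective_concentration(fit, protection)
        assert abs(fraction_affected(fit, pc) - (100.0 - protection)) < 1e-9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(_family_and_params())
    def test_cdf_limits_and_monotonicity(self, fp):
        family, params = fp
        dist = SSDFit(family, params, 10, 0.0, 0.0).dist
        lo, hi = dist.ppf(1e-9), dist.ppf(1 - 1e-9)
        assert dist.cdf(lo) <= 1e-8
        assert dist.cdf(hi) >= 1 - 1e-8
        grid = np.geomspace(max(lo, 1e-300), hi, 50)
        cdf = dist.cdf(grid)
        assert np.all(np.diff(cdf) >= -1e-15)


class TestScaleEquivariance:
    @pytest.mark.parametrize("family", FAMILY_ORDER)
    @pytest.mark.parametrize("k", [0.001, 3.7, 1e4])
    def test_pc_scales_with_concentrations(self, family, k, rng):
        x = _lognormal_sample(rng, n=32)
        base = fit_distribution(x, family)
        scaled = fit_distribution(k * x, family)
        for p in (99.0, 95.0, 90.0, 80.0):
            assert protective_concentration(scaled, p) == pytest.approx(
                k * protective_concentration(base, p), rel=1e-6
            )


class TestBootstrap:
    def test_seed_determinism(self, rng):
        x = _lognormal_sample(rng, n=32)
        a = bootstrap_ci(x, "log_normal", n_boot=500, seed=42)
        b = bootstrap_ci(x, "log_normal", n_boot=500, seed=42)
        assert a == b

    def test_different_seeds_differ(self, rng):
        x = _lognormal_sample(rng, n=32)
        a = bootstrap_ci(x, "log_normal", n_boot=200, seed=1)
        b = bootstrap_ci(x, "log_normal", n_boot=200, seed=2)
        assert a != b

    def test_interval_brackets_point(self, rng):
        x = _lognormal_sample(rng, n=40)
        for est in bootstrap_ci(x, "log_normal", n_boot=1000, seed=3):
            assert est.ci_lower <= est.point <= est.ci_upper

    def test_bootstrap_median_point_mode(self, rng):
        x = _lognormal_sample(rng, n=40)
        fitted = bootstrap_ci(x, "log_normal", n_boot=400, seed=5)
        med = bootstrap_ci(x, "log_normal", n_boot=400, seed=5,
                           pc_point="bootstrap_median")
        for a, b in zip(fitted, med):
            assert b.ci_lower <= b.point <= b.ci_upper
            assert a.ci_lower == b.ci_lower  # same replicate stream

    def test_invalid_n_boot(self, rng):
        x = _lognormal_sample(rng)
        with pytest.raises(ValueError):
            bootstrap_ci(x, "log_normal", n_boot=0, seed=0)


class TestSSDFitterEstimator:
    def test_sklearn_interface(self, rng):
        x = _lognormal_sample(rng, n=32).reshape(-1, 1)
        est = SSDFitter(family="auto").fit(x)
        assert est.family_ in FAMILY_ORDER
        assert est.protective_concentration(99.0) < est.protective_concentration(80.0)
        params = est.get_params()
        assert params["family"] == "auto"
        clone_params = SSDFitter(**params).get_params()
        assert clone_params == params

    def test_forced_family(self, rng):
        x = _lognormal_sample(rng, n=32)
        est = SSDFitter(family="weibull").fit(x)
        assert est.family_ == "weibull"

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            SSDFitter().protective_concentration(95.0)
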