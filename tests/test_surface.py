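"""Temporal adjustment factors and surface assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from trstools.records import SpeciesEntry, SpeciesSensitivitySet
from trstools.surface import (
    ClassMappingError,
    adjust_toxicity,
    build_trs,
    compute_taf_table,
    export_trs_table,
    first_day_below,
    query_surface,
)
from trstools.timetox import TimeResponseRegressor


def _sens_set(values, taxon_class="Insecta"):
    return SpeciesSensitivitySet(
        entries={
            f"sp{i:02d}": SpeciesEntry(
                value=float(v),
                taxon_class=taxon_class,
                medium="freshwater",
                n_source_records=1,
                value_kind="acute_estimated",
            )
            for i, v in enumerate(values)
        }
    )


def _model(intercept=4.6, slope=-1.8):
    return TimeResponseRegressor.from_coefficients(intercept, slope)


@pytest.fixture
def community(rng):
    return np.exp(rng.normal(math.log(100.0), 2.3, size=32))


def _build(values, slope=-1.8, intercept=4.6, measured_day=4.0, **kwargs):
    model = _model(intercept, slope)
    ec_measured = float(model.predict([measured_day])[0])
    kwargs.setdefault("forced_family", {d: "log_normal" for d in range(1, 101)})
    return build_trs(
        _sens_set(values),
        models={"Insecta": model},
        calibration={
            "Insecta": {
                "species": "ref",
                "ec_measured": ec_measured,
                "measured_day": measured_day,
            }
        },
        class_map={"Insecta": "Insecta"},
        **kwargs,
    )


class TestTAF:
    def test_self_calibration_is_unity(self):
        model = _model()
        ec = float(model.predict([4.0])[0])
        taf = compute_taf_table(model, ec, 4.0, days=range(1, 101))
        assert taf.factor(4) == pytest.approx(1.0, rel=1e-12)

    def test_power_law_doubling_ratio(self):
        # TAF(2d)/TAF(d) = 2^slope for every d, by the power law
        model = _model(slope=-1.3)
        taf = compute_taf_table(model, 10.0, 4.0, days=range(1, 101))
        for d in range(1, 51):
            assert taf.factor(2 * d) / taf.factor(d) == pytest.approx(
                2.0**-1.3, rel=1e-12
            )

    def test_slope_minus_one_decade(self):
        model = _model(intercept=math.log(50.0), slope=-1.0)
        taf = compute_taf_table(model, 50.0, 1.0, days=range(1, 11))
        assert taf.factor(10) == pytest.approx(0.1, rel=1e-12)

    def test_strictly_decreasing_for_negative_slope(self):
        taf = compute_taf_table(_model(), 10.0, 4.0, days=range(1, 101))
        f = [taf.factor(d) for d in range(1, 101)]
        assert all(a > b for a, b in zip(f, f[1:]))

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError, match="no time-response model"):
            compute_taf_table(None, 10.0, 4.0, taxon_class="Maxillopoda")


class TestAdjust:
    def test_identity_factor_preserves_values(self, community):
        sens = _sens_set(community)
        model = _model(slope=-1.8)
        ec = float(model.predict([1.0])[0])  # TAF(1) = 1
        taf = compute_taf_table(model, ec, 1.0, days=[1])
        adj = adjust_toxicity(sens, {"Insecta": taf}, {"Insecta": "Insecta"}, 1)
        for sp, e in sens.entries.items():
            assert adj.entries[sp] == pytest.approx(e.value, rel=1e-12)

    def test_multiplicative_form(self):
        sens = _sens_set([100.0] * 8)
        model = _model(intercept=math.log(10.0), slope=-1.0)
        taf = compute_taf_table(model, 10.0, 1.0, days=range(1, 11))
        adj = adjust_toxicity(sens, {"Insecta": taf}, {"Insecta": "Insecta"}, 10)
        assert adj.entries["sp00"] == pytest.approx(10.0, rel=1e-12)

    def test_unmapped_class_lists_species(self, community):
        sens = _sens_set(community, taxon_class="Ostracoda")
        taf = compute_taf_table(_model(), 10.0, 4.0, days=[1])
        with pytest.raises(ClassMappingError, match="Ostracoda"):
            adjust_toxicity(sens, {"Insecta": taf}, {"Insecta": "Insecta"}, 1)

    def test_explicit_exclusion_drops_class(self, community):
        sens = _sens_set(community, taxon_class="Ostracoda")
        taf = compute_taf_table(_model(), 10.0, 4.0, days=[1])
        adj = adjust_toxicity(
            sens, {"Insecta": taf}, {"Ostracoda": "exclude"}, 1
        )
        assert adj.entries == {}


class TestBuildSurface:
    def test_zero_slope_surface_is_time_invariant(self, community):
        surface = _build(community, slope=0.0)
        day1 = surface.slices[1]
        for d in surface.days:
            s = surface.slices[d]
            assert s.fit.params == day1.fit.params
            for level in surface.protection_levels:
                assert s.pcs[level].point == day1.pcs[level].point

    def test_day_one_matches_unadjusted_ssd(self, community):
        # measured_day = 1 makes TAF(1) = 1
        from trstools.ssd import fit_distribution, protective_concentration

        surface = _build(community, measured_day=1.0)
        base = fit_distribution(community, "log_normal")
        for p in surface.protection_levels:
            assert surface.slices[1].pcs[p].point == pytest.approx(
                protective_concentration(base, p), rel=1e-9
            )

    def test_pc_level_ordering_every_day(self, community):
        surface = _build(community)
        for d in surface.days:
            pcs = [surface.slices[d].pcs[p].point for p in (99.0, 95.0, 90.0, 80.0)]
            assert pcs == sorted(pcs)

    def test_pc_nonincreasing_in_day_forced_family(self, community):
        surface = _build(community)
        for level in surface.protection_levels:
            traj = [surface.slices[d].pcs[level].point for d in surface.days]
            assert all(a >= b for a, b in zip(traj, traj[1:]))

    def test_scale_equivariance(self, community):
        k = 137.0
        base = _build(community)
        scaled = _build(k * community)  # calibration rescales implicitly:
        # ec_measured is the model's own prediction, so TAFs are identical
        for d in (1, 17, 50, 100):
            for p in (99.0, 95.0):
                assert scaled.slices[d].pcs[p].point == pytest.approx(
                    k * base.slices[d].pcs[p].point, rel=1e-9
                )

    def test_family_switch_days_reported(self, community):
        forced = {d: ("log_gumbel" if d < 18 else "log_normal") for d in range(1, 101)}
        surface = _build(community, forced_family=forced)
        assert surface.family_switch_days() == [(1, "log_gumbel"), (18, "log_normal")]


class TestQueries:
    def test_pc_paf_round_trip(self, community):
        surface = _build(community)
        pc = query_surface(surface, 28, "pc", 95.0)
        assert query_surface(surface, 28, "paf", pc) == pytest.approx(5.0, abs=1e-9)

    def test_day_out_of_range(self, community):
        surface = _build(community)
        with pytest.raises(ValueError, match="outside surface"):
            query_surface(surface, 101, "pc", 95.0)

    def test_unknown_mode(self, community):
        surface = _build(community)
        with pytest.raises(ValueError, match="mode"):
            query_surface(surface, 1, "hazard", 95.0)

    def test_first_day_below_immediate(self, community):
        surface = _build(community)
        day1_pc95 = surface.slices[1].pcs[95.0].point
        assert first_day_below(surface, 95.0, day1_pc95 * 2) == 1

    def test_first_day_below_matches_scan(self, community):
        surface = _build(community)
        traj = {d: surface.slices[d].pcs[95.0].point for d in surface.days}
        threshold = traj[40]  # strictly between day-39 and day-41 values
        expected = min(d for d, v in traj.items() if v < threshold)
        assert first_day_below(surface, 95.0, threshold) == expected

    def test_never_crossing_returns_none(self, community):
        surface = _build(community)
        assert first_day_below(surface, 95.0, 1e-30) is None


class TestExport:
    def test_hundred_rows_and_round_trip(self, community, tmp_path):
        surface = _build(community)
        path = tmp_path / "trs_table.csv"
        df = export_trs_table(surface, path)
        assert len(df) == 100
        back = pd.read_csv(path, float_precision="round_trip")
        assert len(back) == 100
        # full-precision round trip of the point estimates
        np.testing.assert_array_equal(back["pc95"].to_numpy(), df["pc95"].to_numpy())
        # display columns are 2-significant-figure renderings
        assert back.loc[0, "pc95_display"] == float(f"{df.loc[0, 'pc95']:.2g}")

    def test_byte_identical_reruns(self, community, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        export_trs_table(_build(community, n_boot=50, seed=9), p1)
        export_trs_table(_build(community, n_boot=50, seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()
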