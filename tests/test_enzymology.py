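"""Kinetics, thermal and synergy math."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import kinetics_table, synergy_table
from fragswap import datasets
from fragswap.enzymology import (
    activity_units,
    catalytic_efficiency,
    degree_of_synergy,
    fit_half_life,
    fit_michaelis_menten,
    fit_t50,
    fold_changes,
    kcat_from_vmax,
    percent_change,
)
from fragswap.errors import DomainError, FitError
from fragswap.fixtures import make_decay, make_kinetics, make_t50, make_synergy
from fragswap.formats_io import AssayTable

import pandas as pd


class TestUnitsAndArithmetic:
    def test_unit_definition(self):
        assert activity_units(10.0, 10.0, 1.0) == 1.0
        assert activity_units(6100.0, 10.0, 1.0) == 610.0  # wild-type scale

    def test_proportionality(self):
        assert activity_units(10, 10, 2.0) == activity_units(10, 10, 1.0) / 2

    def test_domain_errors(self):
        for args in [(0, 1, 1), (1, 0, 1), (1, 1, 0)]:
            with pytest.raises(DomainError):
                activity_units(*args)

    def test_kcat_closed_form(self):
        assert kcat_from_vmax(60.0, 1.0) == pytest.approx(1.0)

    def test_kcat_reproduces_wild_type_turnover_in_mass_band(self):
        # a mature mass inside the ~37 kDa band matches the reported 430 /s
        assert kcat_from_vmax(680.0, 37.9) == pytest.approx(429.5, abs=0.05)
        assert round(kcat_from_vmax(680.0, 37.9), 0) == 430

    def test_kcat_reproduces_best_hybrid_turnover(self):
        assert kcat_from_vmax(2200.0, 38.5) == pytest.approx(1411.7, abs=0.05)

    def test_catalytic_efficiency(self):
        assert catalytic_efficiency(430.0, 0.75) == pytest.approx(573.3, abs=0.05)
        assert catalytic_efficiency(740.0, 0.42) == pytest.approx(1761.9, abs=0.05)
        assert catalytic_efficiency(0.0, 1.0) == 0.0
        with pytest.raises(DomainError):
            catalytic_efficiency(1.0, 0.0)

    def test_percent_change(self):
        assert percent_change(2.85, 1.0) == pytest.approx(185.0)
        assert percent_change(1.0, 1.0) == 0.0
        assert percent_change(2.15, 1.0) == pytest.approx(115.0)


class TestMichaelisMenten:
    @pytest.mark.parametrize("km,vmax", [(0.75, 680.0), (0.42, 1160.0)])
    @pytest.mark.parametrize("method", ["lineweaver_burk", "nonlinear"])
    def test_noise_free_recovery_six_significant_digits(self, km, vmax, method):
        table, _ = make_kinetics(0, km=km, vmax=vmax, noise_cv=0.0)
        fit = fit_michaelis_menten(table, method=method)
        assert fit.km == pytest.approx(km, rel=1e-6)
        assert fit.vmax == pytest.approx(vmax, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_lb_and_nonlinear_agree_on_clean_data(self):
        table, _ = make_kinetics(0, km=1.9, vmax=950.0, s_grid=(0.25, 0.8, 1.5, 3.0, 6.0, 12.0))
        lb = fit_michaelis_menten(table, "lineweaver_burk")
        nl = fit_michaelis_menten(table, "nonlinear")
        assert lb.km == pytest.approx(nl.km, rel=1e-6)
        assert lb.vmax == pytest.approx(nl.vmax, rel=1e-6)

    def test_noisy_recovery_median_relative_error(self):
        errs_km, errs_vmax = [], []
        for seed in range(200):
            table, _ = make_kinetics(seed, km=0.75, vmax=680.0, noise_cv=0.05)
            fit = fit_michaelis_menten(table, "nonlinear")
            errs_km.append(abs(fit.km - 0.75) / 0.75)
            errs_vmax.append(abs(fit.vmax - 680.0) / 680.0)
        assert np.median(errs_km) < 0.10
        assert np.median(errs_vmax) < 0.10

    def test_saturated_rates_warn_at_boundary(self):
        table = kinetics_table([0.5, 1, 2, 4, 8, 10], [680.0] * 6)
        with pytest.warns(UserWarning, match="saturated"):
            fit = fit_michaelis_menten(table, "nonlinear")
        assert fit.km == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_rate_rejected_for_reciprocal(self):
        table = kinetics_table([0.5, 1, 2, 4], [10.0, 20.0, 0.0, 40.0])
        with pytest.raises(DomainError):
            fit_michaelis_menten(table, "lineweaver_burk")

    def test_too_few_concentrations(self):
        table = kinetics_table([1, 2, 2, 1], [10, 20, 20, 10])
        with pytest.raises(FitError):
            fit_michaelis_menten(table)


class TestFoldChanges:
    def test_catalytic_efficiency_folds_across_hybrids(self):
        values = {"XylE": datasets.KINETIC_TABLE["XylE"]["kcat_over_km"]}
        values.update({n: datasets.KINETIC_TABLE[n]["kcat_over_km"] for n in datasets.XYLE_HYBRIDS})
        summary = fold_changes(values, reference="XylE")
        assert round(summary.max_fold, 1) == 4.0  # 2280 / 570
        assert round(summary.min_fold, 1) == 2.4  # 1340 / 570
        assert summary.folds["XylE"] == 1.0

    def test_specific_activity_folds(self):
        values = {"XylE": datasets.KINETIC_TABLE["XylE"]["specific_activity"]}
        values.update({n: datasets.KINETIC_TABLE[n]["specific_activity"] for n in datasets.XYLE_HYBRIDS})
        summary = fold_changes(values, reference="XylE")
        assert round(summary.max_fold, 1) == 3.3  # 2010 / 610
        assert round(summary.min_fold, 1) == 1.2  # 730 / 610

    def test_zero_reference_rejected(self):
        with pytest.raises(DomainError):
            fold_changes({"a": 0.0, "b": 1.0}, "a")


class TestThermal:
    @pytest.mark.parametrize("t50", [66.5, 69.5, 70.0, 70.4, 71.2])
    def test_t50_recovery_noise_free(self, t50):
        table, _ = make_t50(0, t50=t50, slope=2.0)
        summary = fit_t50(table)
        assert summary.t50_c == pytest.approx(t50, abs=1e-4)
        assert summary.t50_slope_c == pytest.approx(2.0, abs=1e-4)

    def test_symmetric_three_point_midpoint_interpolation(self):
        table = AssayTable(
            kind="thermal_T50",
            data=pd.DataFrame({"temperature_C": [60.0, 65.0, 70.0], "residual_pct": [100.0, 50.0, 0.0]}),
        )
        assert fit_t50(table, model="interpolate").t50_c == pytest.approx(65.0)

    def test_no_crossing_is_extrapolation_error(self):
        table = AssayTable(
            kind="thermal_T50",
            data=pd.DataFrame({"temperature_C": [30, 35, 40, 45, 50], "residual_pct": [99, 98, 97, 96, 95]}),
        )
        with pytest.raises(FitError, match="50%"):
            fit_t50(table)

    def test_half_life_closed_form(self):
        # R = 100 exp(-ln2 * t) has half-life exactly 1 h
        table, _ = make_decay(0, t_half=1.0)
        assert fit_half_life(table).t_half_h == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("t_half", [1.2, 1.8, 2.3])
    def test_half_life_recovery_noise_free(self, t_half):
        table, _ = make_decay(0, t_half=t_half)
        summary = fit_half_life(table)
        assert summary.t_half_h == pytest.approx(t_half, rel=1e-9)
        assert summary.decay_rate_per_h == pytest.approx(math.log(2) / t_half, rel=1e-9)

    def test_no_decay_warns_with_infinite_half_life(self):
        table = AssayTable(
            kind="thermal_decay",
            data=pd.DataFrame({"time_h": [0, 1, 2, 3], "residual_pct": [100.0, 100.0, 100.0, 100.0]}),
        )
        with pytest.warns(UserWarning, match="no measurable decay"):
            assert fit_half_life(table).t_half_h == math.inf


class TestSynergy:
    def test_additivity_gives_unity(self):
        t = [1, 5, 10, 15]
        cel = [1.0, 2.0, 2.8, 3.2]
        xyl = [0.1, 0.2, 0.35, 0.45]
        both = [c + x for c, x in zip(cel, xyl)]
        result = degree_of_synergy(synergy_table(t, cel, xyl, both))
        assert np.allclose(result.ds, 1.0)

    def test_published_15h_values(self):
        arms = datasets.SYNERGY_15H["XylE-M3/M6"]
        result = degree_of_synergy(
            synergy_table([15.0], [arms["cellulase_only"]], [arms["xylanase_only"]], [arms["both"]])
        )
        assert result.max_ds == pytest.approx(3.9 / (3.2 + 0.45), abs=1e-12)
        assert round(result.max_ds, 3) == 1.068

    def test_double_of_cellulase_alone(self):
        result = degree_of_synergy(synergy_table([1.0], [1.5], [0.0], [3.0]))
        assert result.max_ds == pytest.approx(2.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        t = [1, 5, 10, 15]
        cel = np.array([1.0, 2.0, 2.8, 3.2])
        xyl = np.array([0.1, 0.2, 0.35, 0.45])
        both = np.array([1.2, 2.5, 3.4, 3.9])
        base = degree_of_synergy(synergy_table(t, cel, xyl, both))
        scaled = degree_of_synergy(synergy_table(t, cel * scale, xyl * scale, both * scale))
        assert np.allclose(base.ds, scaled.ds)

    def test_zero_denominator_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            result = degree_of_synergy(synergy_table([1.0, 2.0], [0.0, 1.0], [0.0, 0.5], [0.5, 1.8]))
        assert math.isnan(result.ds[0])
        assert result.ds[1] == pytest.approx(1.2)

    def test_first_crossing_time(self):
        tc, _ = make_synergy(0, ds_profile=lambda t: np.where(t >= 4, 1.2, 0.9))
        result = degree_of_synergy(tc)
        assert result.first_time_ds_above_1 == 4.0

    def test_control_subtraction_option(self):
        table = synergy_table([1.0], [1.1], [0.6], [1.8], ctrl=[0.1])
        raw = degree_of_synergy(table)
        corrected = degree_of_synergy(table, subtract_control=True)
        assert raw.max_ds == pytest.approx(1.8 / 1.7)
        assert corrected.max_ds == pytest.approx(1.7 / 1.5)
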