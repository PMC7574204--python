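"""Batch kinetics, hydrolysate accounting and mass-balance arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scofuel.bioprocess import (
    AnalyteRecord,
    HydrolysateComposition,
    PretreatmentRecord,
    TimeCourse,
    analyze_timecourse,
    consumption_rate,
    detox_loss_percent,
    fold_change,
    hplc_quantify,
    lipid_content,
    mass_balance,
    productivity,
    read_hydrolysate_csv,
    read_timecourse_csv,
    total_sugars,
    utilization_percent,
    write_hydrolysate_csv,
    write_timecourse_csv,
)
from scofuel.errors import (
    CalibrationError,
    ConsistencyError,
    ConsistencyWarning,
    DegenerateInputError,
    DomainError,
)


class TestLipidContent:
    @pytest.mark.parametrize(
        "lipid,dcw,expected",
        [(7.02, 12.56, 55.89), (4.48, 10.63, 42.14), (0.0, 5.0, 0.0)],
    )
    def test_published_batches(self, lipid, dcw, expected):
        assert lipid_content(lipid, dcw) == pytest.approx(expected, abs=0.005)

    def test_zero_dcw_degenerate(self):
        with pytest.raises(DegenerateInputError):
            lipid_content(1.0, 0.0)

    def test_lipid_above_dcw_inconsistent(self):
        with pytest.raises(ConsistencyError):
            lipid_content(6.0, 5.0)


class TestRates:
    @pytest.mark.parametrize(
        "dconc,dt,expected",
        [(7.02, 120, 0.0585), (4.48, 120, 0.0373), (0.0, 77, 0.0)],
    )
    def test_productivity(self, dconc, dt, expected):
        assert productivity(dconc, dt) == pytest.approx(expected, abs=5e-5)

    def test_productivity_needs_positive_interval(self):
        with pytest.raises(DomainError):
            productivity(1.0, 0.0)

    @pytest.mark.parametrize(
        "initial,final,dt,expected",
        [(30, 0, 120, 0.25), (5, 5, 10, 0.0), (37.38, 31.91, 120, 0.0456)],
    )
    def test_consumption_rate(self, initial, final, dt, expected):
        assert consumption_rate(initial, final, dt) == pytest.approx(expected, abs=5e-5)

    def test_net_production_warns(self):
        with pytest.warns(ConsistencyWarning):
            rate = consumption_rate(1.0, 2.0, 10.0)
        assert rate == pytest.approx(-0.1)

    @settings(derandomize=True)
    @given(
        st.lists(st.floats(0.1, 20.0), min_size=2, max_size=6),
        st.lists(st.floats(0.0, 5.0), min_size=2, max_size=6),
    )
    def test_rates_additive_over_adjacent_windows(self, dts, deltas):
        """Whole-interval rate equals the time-weighted mean of sub-window rates."""
        n = min(len(dts), len(deltas))
        dts, deltas = dts[:n], deltas[:n]
        total_dt, total_delta = sum(dts), sum(deltas)
        weighted = sum(productivity(d, t) * t for d, t in zip(deltas, dts)) / total_dt
        assert productivity(total_delta, total_dt) == pytest.approx(weighted, rel=1e-9)


class TestUtilizationAndFolds:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(107, 6.3, 94.11), (0.37, 0.24, 35.14), (1.53, 0.38, 75.16), (4.0, 4.0, 0.0)],
    )
    def test_trace_element_utilization(self, before, after, expected):
        assert utilization_percent(before, after) == pytest.approx(expected, abs=0.005)

    def test_zero_before_degenerate(self):
        with pytest.raises(DegenerateInputError):
            utilization_percent(0.0, 0.0)

    @settings(derandomize=True)
    @given(st.floats(0.01, 1e3), st.floats(0.0, 1.0))
    def test_bounded_when_after_below_before(self, before, frac):
        assert -1e-9 <= utilization_percent(before, before * frac) <= 100.0 + 1e-9

    @pytest.mark.parametrize(
        "a,b,expected", [(7.43, 6.26, 1.187), (107, 6.3, 16.98), (3.3, 3.3, 1.0)]
    )
    def test_fold_change(self, a, b, expected):
        assert fold_change(a, b) == pytest.approx(expected, abs=0.005)

    def test_fold_change_zero_denominator(self):
        with pytest.raises(DomainError):
            fold_change(1.0, 0.0)


class TestSugarAccounting:
    def test_as_psh_total(self):
        assert total_sugars((28.05, 18.13, 0.29)) == pytest.approx(46.47)

    def test_ad_psh_total(self):
        assert total_sugars((0.45, 29.01, 2.45)) == pytest.approx(31.91)

    def test_empty_total(self):
        assert total_sugars(()) == 0.0

    def test_composition_total_converts_units(self):
        comp = HydrolysateComposition(
            {
                "glucose": AnalyteRecord("g/L", 10.0, None),
                "xylose": AnalyteRecord("mg/L", 500.0, None),
            }
        )
        assert total_sugars(comp, sugar_names=("glucose", "xylose")) == pytest.approx(10.5)

    @pytest.mark.parametrize(
        "before,after,expected",
        [(37.38, 31.91, 14.63), (5.61, 0.11, 98.04), (8.0, 8.0, 0.0)],
    )
    def test_detox_loss(self, before, after, expected):
        assert detox_loss_percent(before, after) == pytest.approx(expected, abs=0.005)

    def test_pretreatment_record_invariant(self):
        with pytest.raises(ConsistencyError):
            PretreatmentRecord("acid-liquid", 20.0, 30.0, 31.0)


class TestHPLC:
    def test_definition_and_linearity(self):
        assert hplc_quantify(1000.0, 1000.0) == pytest.approx(1.0)
        assert hplc_quantify(2000.0, 1000.0) == pytest.approx(2.0)
        assert hplc_quantify(0.0, 1234.0) == 0.0

    def test_zero_standard_area(self):
        with pytest.raises(CalibrationError):
            hplc_quantify(100.0, 0.0)


class TestMassBalance:
    def test_published_row(self):
        mb = mass_balance(20, 12.8, 6.8, 0.9177)
        assert mb.shells_g_l == pytest.approx(200.0)
        assert mb.biodiesel_g_l == pytest.approx(6.24, abs=0.005)
        assert mb.lipid_content_pct == pytest.approx(53.1, abs=0.05)

    def test_zero_lipid_gives_zero_biodiesel(self):
        assert mass_balance(20, 10.0, 0.0, 0.9).biodiesel_g_l == 0.0

    def test_chain_non_increasing(self):
        mb = mass_balance(20, 12.8, 6.8, 0.9177)
        stages = mb.stages()
        assert all(a >= b for a, b in zip(stages, stages[1:]))

    def test_efficiency_domain(self):
        with pytest.raises(DomainError):
            mass_balance(20, 10, 5, 1.2)


class TestTimeCourse:
    def _tc(self):
        return TimeCourse(
            times=[0, 60, 120],
            dcw=[0.1, 8.0, 12.56],
            lipid_titre=[0.0, 3.0, 7.02],
            sugars={"glucose": [28.05, 14.0, 0.0]},
        )

    def test_endpoint_kinetics(self):
        kin = analyze_timecourse(self._tc())
        assert kin.lipid_productivity == pytest.approx((7.02 - 0.0) / 120)
        assert kin.biomass_productivity == pytest.approx((12.56 - 0.1) / 120)
        assert kin.lipid_content == pytest.approx(55.89, abs=0.005)
        assert kin.consumption_rates["glucose"] == pytest.approx(28.05 / 120)

    def test_windowed_kinetics(self):
        kin = analyze_timecourse(self._tc(), window=(60.0, 120.0))
        assert kin.lipid_productivity == pytest.approx((7.02 - 3.0) / 60)
        assert kin.window == (60.0, 120.0)

    def test_max_slope_mode(self):
        kin = analyze_timecourse(self._tc(), mode="max-slope")
        assert kin.biomass_productivity == pytest.approx((8.0 - 0.1) / 60)

    def test_initial_sugar_from_recipe(self):
        """The medium recipe supplies t=0 sugar when the trajectory lacks it."""
        tc = TimeCourse(
            times=[0, 120],
            dcw=[0.1, 12.26],
            lipid_titre=[0.0, 6.65],
            sugars={"glucose": [0.0, 0.0]},  # no t=0 sample recorded
        )
        kin = analyze_timecourse(tc, initial_sugars={"glucose": 30.0})
        assert kin.consumption_rates["glucose"] == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(times=[10, 60], dcw=[1, 2], lipid_titre=[0, 1]),  # t0 != 0
            dict(times=[0, 0], dcw=[1, 2], lipid_titre=[0, 1]),  # not increasing
            dict(times=[0, 60], dcw=[1, 2], lipid_titre=[0, 3]),  # lipid > dcw
            dict(times=[0, 60], dcw=[1, -2], lipid_titre=[0, 0]),  # negative
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises((DomainError, ConsistencyError)):
            TimeCourse(**kwargs)

    def test_csv_round_trip(self, tmp_path):
        tc = self._tc()
        path = tmp_path / "tc.csv"
        write_timecourse_csv(tc, path)
        back = read_timecourse_csv(path)
        np.testing.assert_allclose(back.dcw, tc.dcw)
        np.testing.assert_allclose(back.sugars["glucose"], tc.sugars["glucose"])


class TestHydrolysateComposition:
    def test_not_detected_is_missing_not_zero(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text(
            "analyte,unit,before,after\n"
            "glucose,g/L,28.05,ND\n"
            "calcium,mg/L,107,6.3\n"
            "furfural,g/L,,\n"
        )
        comp = read_hydrolysate_csv(path)
        assert comp.analytes["glucose"].after is None
        assert comp.analytes["furfural"].before is None
        # furfural (never measured before cultivation) is excluded entirely
        assert "furfural" not in comp.utilization_table()
        # fully consumed analytes count as 100 % utilized
        assert comp.utilization("glucose") == pytest.approx(100.0)
        assert comp.utilization("calcium") == pytest.approx(94.11, abs=0.005)

    def test_round_trip(self, tmp_path):
        comp = HydrolysateComposition(
            {
                "glucose": AnalyteRecord("g/L", 28.05, None),
                "calcium": AnalyteRecord("mg/L", 107.0, 6.3),
            }
        )
        path = tmp_path / "h.csv"
        write_hydrolysate_csv(comp, path)
        back = read_hydrolysate_csv(path)
        assert back.analytes["glucose"].after is None
        assert back.analytes["calcium"].after == pytest.approx(6.3)
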