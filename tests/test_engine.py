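"""Engine: mode dispatch, notifications, forecast flagging, sensitivity grid."""

from datetime import datetime, timezone

import pytest
from hypothesis import given, settings, strategies as st

from climstress import (
    IndoorEnvironment,
    PersonContext,
    PersonProfile,
    WeatherSample,
    activity_profile,
    assess,
    clothing_catalogue,
    decision_tree,
    forecast_indices,
    generate_synthetic_forecast,
    sensitivity_grid,
)
from climstress.cold import ColdAssessment
from climstress.engine import Assessment, NOTIFICATION_CATALOGUE
from climstress.heat import HeatAssessment, heat_index, hrl_category


PERSON = PersonProfile(age=35, height=180.0, weight=80.0, sex="male")


def _context(level="moderate", clothing="summer", person=PERSON, indoor=None, perception=None):
    return PersonContext(
        person=person,
        activity=activity_profile(level, person),
        clothing=clothing_catalogue(clothing),
        indoor=indoor,
        perception=perception,
    )


def _sample(t_air, v10=2.0, rh=50.0, cloud=0.0, hour=12, lat=45.0, lon=0.0):
    return WeatherSample(
        t_air=t_air, rh=rh, p_air=101.3, v10=v10, cloud=cloud, lat=lat, lon=lon,
        timestamp=datetime(2021, 6, 21, hour, tzinfo=timezone.utc),
    )


def _codes(assessment):
    return [n.code for n in assessment.notifications]


class TestModeDispatch:
    def test_hot_scenario_heat_mode(self):
        series = generate_synthetic_forecast(1, "heatwave")
        a = assess(series[4], _context("moderate", "summer"))
        assert a.mode == "heat"
        assert a.index >= 1.0
        assert a.heat is not None and a.cold is None

    def test_arctic_overdressed_paradox(self):
        # overdressed in severe cold: positive index plus frostbite notice
        series = generate_synthetic_forecast(1, "arctic")
        a = assess(series[3], _context("high", "extreme-winter"))
        assert a.mode == "cold"
        assert a.index > 0.0
        assert a.cold.frostbite_flag
        assert "cold.frostbite_risk" in _codes(a)

    def test_indoor_dispatch(self):
        env = IndoorEnvironment(t_air_indoor=22.0, rh_indoor=50.0)
        a = assess(_sample(30.0), _context("low", "casual", indoor=env))
        assert a.mode == "indoor"
        assert a.index == pytest.approx(a.indoor.pmv)
        assert a.heat is None and a.cold is None

    def test_phs_attached_in_hot_envelope(self):
        series = generate_synthetic_forecast(1, "heatwave")
        a = assess(series[4], _context("high", "summer"))
        assert a.mode == "heat" and a.phs is not None

    @settings(max_examples=20, deadline=None)
    @given(t_air=st.floats(-35.0, 45.0), v10=st.floats(0.0, 12.0), cloud=st.floats(0, 8))
    def test_dispatch_total_and_index_bounded(self, t_air, v10, cloud):
        a = assess(_sample(t_air, v10=v10, cloud=cloud), _context("moderate", "casual"))
        assert a.mode in {"heat", "cold"}
        assert -4.0 <= a.index <= 4.0
        assert (a.mode == "heat") == (a.heat is not None)
        assert (a.mode == "cold") == (a.cold is not None)


def _heat_assessment(hrl, cav_value):
    return Assessment(
        mode="heat",
        index=heat_index(hrl),
        weather=_sample(32.0),
        heat=HeatAssessment(
            wbgt_effective=25.0, cav=cav_value, wbgt_ref=25.0, hrl=hrl,
            category=hrl_category(hrl), index=heat_index(hrl),
        ),
    )


def _cold_assessment(t_air, t_windchill, icl_neutral=2.0, icl_minimal=1.5, dle=None):
    return Assessment(
        mode="cold",
        index=0.0,
        weather=_sample(t_air, hour=0),
        cold=ColdAssessment(
            icl_neutral=icl_neutral, icl_minimal=icl_minimal, dle_cold=dle,
            t_windchill=t_windchill, index=0.0, frostbite_flag=t_windchill < 0.0,
        ),
    )


class TestDecisionTree:
    def test_cold_wind_stopper_and_frostbite(self):
        a = _cold_assessment(-5.0, -12.0)
        codes = [n.code for n in decision_tree(a, _context("low", "winter"))]
        assert "cold.wind_stopper" in codes
        assert "cold.frostbite_risk" in codes

    def test_wind_stopper_gate_is_two_degrees(self):
        ctx = _context("low", "winter")
        below = [n.code for n in decision_tree(_cold_assessment(5.0, 3.1), ctx)]
        at = [n.code for n in decision_tree(_cold_assessment(5.0, 3.0), ctx)]
        assert "cold.wind_stopper" in at
        assert "cold.wind_stopper" not in below
        assert "cold.frostbite_risk" not in at  # windchill still above freezing

    def test_heat_gates_closed_for_light_clothing_low_activity(self):
        codes = [n.code for n in decision_tree(_heat_assessment(0.9, -0.9), _context("low"))]
        assert "heat.adjust_clothing" not in codes
        assert "heat.reschedule_work" not in codes
        assert "heat.alert_approaching" in codes
        assert "heat.hydrate" in codes

    def test_heat_gates_open_for_heavy_clothing_high_activity(self):
        codes = [n.code for n in decision_tree(_heat_assessment(1.1, 2.5), _context("high"))]
        assert "heat.adjust_clothing" in codes
        assert "heat.reschedule_work" in codes
        assert "heat.alert_approaching" not in codes  # past the approach band
        assert "heat.cooling_vest" in codes

    def test_underdressed_emits_exposure_minutes(self):
        a = _cold_assessment(-20.0, -30.0, icl_minimal=2.5, dle=45.0)
        ctx = _context("low", "casual")  # 0.8 Clo worn, below minimal
        notes = decision_tree(a, ctx)
        dle_notes = [n for n in notes if n.code == "cold.underdressed_dle"]
        assert dle_notes and dle_notes[0].params["minutes"] == 45.0

    def test_overdressed_emits_sweat_prevention(self):
        a = _cold_assessment(-2.0, -2.0, icl_neutral=1.0, icl_minimal=0.5)
        notes = decision_tree(a, _context("moderate", "extreme-winter"))
        assert "cold.overdressed_sweat" in [n.code for n in notes]

    def test_caregiver_profile_changes_audience_not_codes(self):
        carer = PersonProfile(
            age=35, height=180.0, weight=80.0, sex="male", profile="senior-caregiver"
        )
        a = _heat_assessment(0.9, 2.0)
        personal = decision_tree(a, _context("moderate"))
        caregiver = decision_tree(a, _context("moderate", person=carer))
        assert [n.code for n in personal] == [n.code for n in caregiver]
        assert all(n.audience == "senior-caregiver" for n in caregiver)

    def test_all_emitted_codes_catalogued(self):
        for a in (_heat_assessment(1.1, 2.5), _cold_assessment(-5.0, -12.0)):
            for ctx in (_context("rest"), _context("very-high")):
                for n in decision_tree(a, ctx):
                    assert n.code in NOTIFICATION_CATALOGUE

    def test_perception_echo_never_moves_index(self):
        series = generate_synthetic_forecast(1, "heatwave")
        plain = assess(series[4], _context("moderate", "summer"))
        felt = assess(series[4], _context("moderate", "summer", perception=-3))
        assert felt.index == plain.index
        assert "perception.sensitivity" in _codes(felt)


class TestForecast:
    def test_temperate_has_no_flagged_windows(self):
        series = generate_synthetic_forecast(1, "temperate")
        _, windows = forecast_indices(series, _context("moderate", "casual"))
        assert windows == []

    def test_heatwave_flags_midday_window(self):
        series = generate_synthetic_forecast(1, "heatwave")
        assessments, windows = forecast_indices(series, _context("moderate", "summer"))
        assert len(windows) == 1
        peak = max(assessments, key=lambda a: a.index)
        w = windows[0]
        assert w["start"] <= peak.weather.timestamp <= w["end"]

    def test_peak_cold_strain_can_miss_coldest_hour(self):
        # strong evening wind: the mildest-but-windiest hour is the worst
        ctx = _context("low", "winter")
        samples = [
            WeatherSample(
                t_air=t, rh=70.0, p_air=100.5, v10=v, cloud=6.0, lat=69.6, lon=18.9,
                timestamp=datetime(2021, 1, 20, h, tzinfo=timezone.utc),
            )
            for h, t, v in [(10, -6.0, 2.0), (13, -9.0, 1.0), (16, -5.0, 4.0),
                            (19, -4.0, 8.0), (22, -3.0, 12.0)]
        ]
        from climstress import ForecastSeries

        assessments, _ = forecast_indices(ForecastSeries(samples=samples), ctx)
        coldest_air = min(assessments, key=lambda a: a.weather.t_air)
        worst = min(assessments, key=lambda a: a.index)
        assert worst.weather.timestamp != coldest_air.weather.timestamp
        assert worst.weather.t_air > coldest_air.weather.t_air


class TestSensitivityGrid:
    LIGHT = clothing_catalogue("light", icl=0.6 * 0.155, im_st=0.38, p_air_perm=50.0)
    WARM = clothing_catalogue("cold-weather", icl=1.5 * 0.155, im_st=0.38, p_air_perm=5.0)
    T_RANGE = [-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0]

    def test_acclimatisation_shifts_heat_onset_upward(self):
        g_no = sensitivity_grid(self.T_RANGE, ["moderate"], self.LIGHT, False)
        g_yes = sensitivity_grid(self.T_RANGE, ["moderate"], self.LIGHT, True)
        onset = lambda g: min(
            (r.t_air for r in g.itertuples() if r.mode == "heat" and r.index >= 1.0),
            default=None,
        )
        assert onset(g_yes) >= onset(g_no)
        heat_rows = g_no["mode"] == "heat"
        assert all(g_yes["index"][heat_rows] <= g_no["index"][heat_rows] + 1e-9)

    def test_winter_clothing_removes_cold_band_at_0_to_10(self):
        cold_band = [0.0, 5.0, 10.0]
        for level in ("moderate", "high"):
            light = sensitivity_grid(cold_band, [level], self.LIGHT, False)
            warm = sensitivity_grid(cold_band, [level], self.WARM, False)
            assert all(warm["index"] >= light["index"] - 1e-9)
            assert all(warm["index"] >= -0.5)  # cold issues gone with 1.5 Clo

    def test_columns_monotone_in_heat_regime(self):
        g = sensitivity_grid(self.T_RANGE, ["moderate", "high"], self.LIGHT, False)
        for level, sub in g.groupby("activity"):
            heat = sub[sub["mode"] == "heat"].sort_values("t_air")
            assert heat["index"].is_monotonic_increasing

    def test_rh_capped_at_cold_temperatures(self):
        # the fixed vapour pressure exceeds saturation below ~9 degC; the
        # grid must still be computable and bounded there
        g = sensitivity_grid([-20.0, -10.0, 0.0], ["low"], self.WARM, False)
        assert ((g["index"] >= -4.0) & (g["index"] <= 4.0)).all()
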