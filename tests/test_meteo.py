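"""Derived meteorology: vapour pressure, wind profile, solar chain, clouds.

The solar-position cross-check pits the package's almanac algorithm
(Michalsky-style mean elements + sidereal time) against an independently
written NOAA/Meeus-style calculator implemented below.
"""

import math
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings, strategies as st

from climstress import (
    cloud_transmittance,
    solar_position,
    solar_radiation,
    suggested_indoor_rh,
    vapour_pressure,
    wind_at_2m,
)
from climstress.meteo import SolarGeometry, saturation_vapour_pressure


class TestVapourPressure:
    def test_dry_air_is_zero(self):
        assert vapour_pressure(20.0, 0.0) == 0.0

    def test_reference_value(self):
        # 0.1 * 0.5 * exp(18.965 - 4030/255) = 1.1798 kPa
        assert vapour_pressure(20.0, 50.0) == pytest.approx(1.1798, abs=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(
        t=st.floats(-40.0, 50.0),
        rh=st.floats(1.0, 100.0),
        dt=st.floats(0.1, 5.0),
        drh=st.floats(0.1, 10.0),
    )
    def test_monotone_in_both_arguments(self, t, rh, dt, drh):
        base = vapour_pressure(t, rh)
        assert vapour_pressure(t + dt, rh) > base
        if rh + drh <= 100.0:
            assert vapour_pressure(t, rh + drh) > base

    def test_domain_error(self):
        with pytest.raises(ValueError):
            vapour_pressure(-240.0, 50.0)


class TestWindProfile:
    def test_zero_maps_to_zero(self):
        assert wind_at_2m(0.0) == 0.0

    def test_printed_rounding(self):
        assert round(wind_at_2m(1.0), 2) == 0.67

    def test_exact_power_form(self):
        assert wind_at_2m(3.0) == pytest.approx(3.0 * 0.2**0.25, rel=1e-12)
        assert wind_at_2m(1.0) == pytest.approx(0.66874, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            wind_at_2m(-0.1)


# --- independent NOAA/Meeus-style solar position (oracle) ------------------

def _noaa_solar_elevation(lat, lon, when: datetime) -> float:
    when = when.astimezone(timezone.utc)
    j2000 = datetime(2000, 1, 1, 12, tzinfo=timezone.utc)
    jd = 2451545.0 + (when - j2000).total_seconds() / 86400.0
    jc = (jd - 2451545.0) / 36525.0
    gmls = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    g = math.radians(gmas)
    seqc = (
        math.sin(g) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * g) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * g) * 0.000289
    )
    stl = gmls + seqc
    sal = stl - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    moe = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    oc = moe + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.asin(math.sin(math.radians(oc)) * math.sin(math.radians(sal)))
    vary = math.tan(math.radians(oc / 2.0)) ** 2
    eqtime = 4.0 * math.degrees(
        vary * math.sin(2 * math.radians(gmls))
        - 2 * eeo * math.sin(g)
        + 4 * eeo * vary * math.sin(g) * math.cos(2 * math.radians(gmls))
        - 0.5 * vary * vary * math.sin(4 * math.radians(gmls))
        - 1.25 * eeo * eeo * math.sin(2 * g)
    )
    minutes = when.hour * 60 + when.minute + when.second / 60.0
    tst = (minutes + eqtime + 4.0 * lon) % 1440.0
    ha = math.radians(tst / 4.0 - 180.0)
    phi = math.radians(lat)
    cos_zen = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(ha)
    return 90.0 - math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))


class TestSolarPosition:
    def test_distance_formula_consistency(self):
        # d must satisfy 1.00014 - 0.01671 cos(a) - 0.00014 cos(2a) at the
        # returned mean anomaly, and perihelion/aphelion bound it
        for day in range(0, 365, 30):
            when = datetime(2021, 1, 1, tzinfo=timezone.utc) + timedelta(days=day)
            geom = solar_position(50.0, 10.0, when)
            a = math.radians(geom.mean_anomaly_deg)
            expected = 1.00014 - 0.01671 * math.cos(a) - 0.00014 * math.cos(2 * a)
            assert geom.d_solar == pytest.approx(expected, abs=1e-12)
            assert 0.983 <= geom.d_solar <= 1.017

    def test_equator_equinox_noon_overhead(self):
        geom = solar_position(0.0, 0.0, datetime(2021, 3, 20, 12, 8, tzinfo=timezone.utc))
        assert geom.cza == pytest.approx(1.0, abs=0.01)

    def test_midnight_sun_below_horizon(self):
        geom = solar_position(45.0, 0.0, datetime(2021, 6, 21, 0, 0, tzinfo=timezone.utc))
        assert geom.elevation_deg < 0.0
        q_solar, q_toa = solar_radiation(geom)
        assert q_solar == 0.0 and q_toa == 0.0

    def test_against_independent_algorithm(self):
        # year-long grid of sites x times, 2 degree agreement
        sites = [(0.0, 0.0), (55.7, 12.6), (69.65, 18.96), (-33.9, 151.2), (37.98, -122.0)]
        worst = 0.0
        for lat, lon in sites:
            for day in range(0, 365, 21):
                for hour in (0, 6, 12, 18):
                    when = datetime(2021, 1, 3, hour, tzinfo=timezone.utc) + timedelta(days=day)
                    ours = solar_position(lat, lon, when).elevation_deg
                    ref = _noaa_solar_elevation(lat, lon, when)
                    worst = max(worst, abs(ours - ref))
        assert worst < 2.0


class TestSolarRadiation:
    def test_overhead_values(self):
        q_solar, q_toa = solar_radiation(SolarGeometry(90.0, 1.0, 1.0, 0.0))
        assert q_toa == pytest.approx(1367.0)
        assert q_solar == pytest.approx(1161.95)

    def test_below_horizon_clamped(self):
        q_solar, q_toa = solar_radiation(SolarGeometry(-17.0, -0.3, 1.0, 0.0))
        assert q_solar == 0.0 and q_toa == 0.0

    def test_linear_in_cza(self):
        full, _ = solar_radiation(SolarGeometry(90.0, 1.0, 1.0, 0.0))
        half, _ = solar_radiation(SolarGeometry(30.0, 0.5, 1.0, 0.0))
        assert half == pytest.approx(full / 2.0)

    @settings(max_examples=40, deadline=None)
    @given(cza=st.floats(-1.0, 1.0), d=st.floats(0.983, 1.017))
    def test_upper_bound(self, cza, d):
        q_solar, _ = solar_radiation(SolarGeometry(0.0, cza, d, 0.0))
        assert 0.0 <= q_solar <= 1367.0 * 0.85 / d**2 + 1e-9


class TestCloudTransmittance:
    @pytest.mark.parametrize(
        "octa,expected",
        [(0.0, 1.0), (8.0, 0.25), (4.0, 1.0 - 0.75 * 0.5**3.4)],
    )
    def test_values(self, octa, expected):
        assert cloud_transmittance(octa) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(n=st.floats(0.0, 8.0))
    def test_bounded(self, n):
        assert 0.25 <= cloud_transmittance(n) <= 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            cloud_transmittance(9.0)


class TestIndoorHumiditySuggestion:
    def test_self_consistent(self):
        pv = vapour_pressure(20.0, 50.0)
        assert suggested_indoor_rh(20.0, pv) == pytest.approx(50.0, abs=1e-9)

    def test_warmer_air_lower_rh(self):
        pv = vapour_pressure(20.0, 50.0)
        assert suggested_indoor_rh(25.0, pv) < 50.0

    def test_saturation_cap(self):
        pv = vapour_pressure(20.0, 100.0)
        assert suggested_indoor_rh(10.0, pv) == 100.0

    def test_consistent_with_saturation_curve(self):
        pv = vapour_pressure(18.0, 80.0)
        expected = 100.0 * pv / saturation_vapour_pressure(25.0)
        assert suggested_indoor_rh(25.0, pv) == pytest.approx(expected)
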