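"""Model-grade environmental variables derived from a raw weather sample.

The thermal models need quantities a standard forecast does not carry:
water vapour pressure (Antoine relation), wind at 2 m (1/4-power profile,
neutral stability), total solar radiation (clear-sky fraction of
top-of-atmosphere irradiance from solar geometry) and the cloud
transmittance that attenuates it.  The solar position uses the low-precision
astronomical-almanac algorithm (mean longitude / mean anomaly / sidereal
time), good to a fraction of a degree - far inside what the globe model
needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

from .weather_io import WeatherSample

__all__ = [
    "SOLAR_CONSTANT",
    "CLEAR_SKY_TRANSMISSION",
    "SolarGeometry",
    "MeteoDerived",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "wind_at_2m",
    "solar_position",
    "solar_radiation",
    "cloud_transmittance",
    "suggested_indoor_rh",
    "derive",
]

SOLAR_CONSTANT = 1367.0  # W/m2
CLEAR_SKY_TRANSMISSION = 0.85  # max atmospheric transmission of TOA radiation

_WIND_PROFILE_FACTOR = (2.0 / 10.0) ** 0.25  # ~0.669, printed as 0.67


@dataclass(frozen=True)
class SolarGeometry:
    """Solar elevation, cosine zenith angle, Earth-Sun distance, mean anomaly."""

    elevation_deg: float
    cza: float
    d_solar: float  # A.U.
    mean_anomaly_deg: float


@dataclass(frozen=True)
class MeteoDerived:
    """Derived environmental variables for one weather sample."""

    pv_air: float  # kPa
    v2: float  # m/s
    q_solar: float  # W/m2, clear-sky total at the surface
    q_solar_toa: float  # W/m2
    transmittance: float  # cloud transmittance ratio, 0.25..1
    geometry: SolarGeometry


def saturation_vapour_pressure(t_air: float) -> float:
    """Saturated water vapour pressure (kPa) by the Antoine relation."""
    if t_air <= -235.0:
        raise ValueError("air temperature outside Antoine-relation domain")
    return 0.1 * math.exp(18.965 - 4030.0 / (t_air + 235.0))


def vapour_pressure(t_air: float, rh: float) -> float:
    """Ambient water vapour pressure (kPa) from temperature and RH (%)."""
    if not 0.0 <= rh <= 100.0:
        raise ValueError("relative humidity must be within 0..100%")
    return (rh / 100.0) * saturation_vapour_pressure(t_air)


def wind_at_2m(v10: float) -> float:
    """Scale 10 m wind to 2 m with the (2/10)^0.25 neutral-stability profile."""
    if v10 < 0.0:
        raise ValueError("wind speed must be non-negative")
    return v10 * _WIND_PROFILE_FACTOR


def solar_position(lat: float, lon: float, timestamp: datetime) -> SolarGeometry:
    """Low-precision almanac solar position for a UTC timestamp.

    Mean longitude, mean anomaly, ecliptic longitude, declination and
    Greenwich sidereal time follow the Astronomical Almanac low-precision
    formulae; the hour angle comes from UTC plus longitude, so no timezone
    database is involved.  The Earth-Sun distance is
    ``1.00014 - 0.01671 cos(g) - 0.00014 cos(2g)`` with ``g`` the mean
    anomaly.
    """
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=timezone.utc)
    t = timestamp.astimezone(timezone.utc)
    # days since J2000.0 (2000-01-01 12:00 UT)
    j2000 = datetime(2000, 1, 1, 12, 0, 0, tzinfo=timezone.utc)
    delta = (t - j2000).total_seconds() / 86400.0

    g = math.radians((357.528 + 0.9856003 * delta) % 360.0)  # mean anomaly
    q = (280.460 + 0.9856474 * delta) % 360.0  # mean longitude
    lam = math.radians(q + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 0.0000004 * delta)  # obliquity

    decl = math.asin(math.sin(eps) * math.sin(lam))
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))  # radians

    ut_hours = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    gmst = (6.697375 + 0.0657098242 * delta + ut_hours) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = math.radians(lmst * 15.0) - ra  # hour angle
    ha = math.atan2(math.sin(ha), math.cos(ha))  # wrap to [-pi, pi]

    phi = math.radians(lat)
    sin_el = math.sin(decl) * math.sin(phi) + math.cos(decl) * math.cos(phi) * math.cos(ha)
    sin_el = max(-1.0, min(1.0, sin_el))
    elevation = math.degrees(math.asin(sin_el))

    d_solar = 1.00014 - 0.01671 * math.cos(g) - 0.00014 * math.cos(2 * g)
    cza = math.cos(math.radians(90.0 - elevation))
    return SolarGeometry(
        elevation_deg=elevation,
        cza=cza,
        d_solar=d_solar,
        mean_anomaly_deg=math.degrees(g) % 360.0,
    )


def solar_radiation(geom: SolarGeometry) -> tuple[float, float]:
    """Clear-sky surface and top-of-atmosphere radiation (W/m2).

    TOA is ``G_sc * max(0, cza / d^2)`` (the clamp zeroes the sun below the
    horizon); the surface value applies the maximum atmospheric transmission
    of 0.85.
    """
    q_toa = SOLAR_CONSTANT * max(0.0, geom.cza / geom.d_solar**2)
    return CLEAR_SKY_TRANSMISSION * q_toa, q_toa


def cloud_transmittance(n_octa: float) -> float:
    """Solar transmittance ratio for cloud cover in octa: 1 - 0.75 (N/8)^3.4."""
    if not 0.0 <= n_octa <= 8.0:
        raise ValueError("cloud cover must be within 0..8 octa")
    return 1.0 - 0.75 * (n_octa / 8.0) ** 3.4


def suggested_indoor_rh(t_indoor_suggested: float, pv_air_outdoor: float) -> float:
    """Suggested indoor RH (%): outdoor vapour pressure over indoor saturation.

    Assumes indoor absolute humidity equals outdoor (natural ventilation);
    capped at 100%.
    """
    psat = saturation_vapour_pressure(t_indoor_suggested)
    return min(100.0, 100.0 * pv_air_outdoor / psat)


def derive(sample: WeatherSample) -> MeteoDerived:
    """Compute all derived variables for one weather sample."""
    geom = solar_position(sample.lat, sample.lon, sample.timestamp)
    q_solar, q_toa = solar_radiation(geom)
    return MeteoDerived(
        pv_air=vapour_pressure(sample.t_air, sample.rh),
        v2=wind_at_2m(sample.v10),
        q_solar=q_solar,
        q_solar_toa=q_toa,
        transmittance=cloud_transmittance(sample.cloud),
        geometry=geom,
    )
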