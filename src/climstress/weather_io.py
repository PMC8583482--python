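"""Forecast parsing, validation and synthetic weather generation.

Weather input arrives as JSON in a dialect mirroring the OpenWeatherMap
5-day/3-hour forecast schema (one object per 3 h step).  All fields are
unit-normalised at the boundary: pressure hPa -> kPa, percent cloudiness ->
octa (nearest eighth), optional km/h wind -> m/s.  Internally cloud cover is
always octa and timestamps are always UTC.

A deterministic synthetic-forecast generator stands in for the live weather
service so the whole assessment pipeline is testable offline.
"""

from __future__ import annotations

import json
import math
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "WeatherSample",
    "ForecastSeries",
    "read_forecast",
    "write_forecast",
    "generate_synthetic_forecast",
    "SCENARIOS",
]


class WeatherSample(BaseModel):
    """One forecast time-point of raw meteorological fields.

    Units: ``t_air`` degC, ``rh`` % (0-100), ``p_air`` kPa, ``v10`` m/s at
    10 m, ``cloud`` octa (0-8), ``rain`` ml, ``snow`` cm.
    """

    t_air: float
    rh: float = Field(ge=0.0, le=100.0)
    p_air: float = Field(gt=0.0)
    v10: float = Field(ge=0.0)
    cloud: float = Field(ge=0.0, le=8.0)
    rain: float = 0.0
    snow: float = 0.0
    lat: float = Field(ge=-90.0, le=90.0)
    lon: float = Field(gt=-180.0, le=180.0)
    timestamp: datetime

    @field_validator("timestamp")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        if v.tzinfo is None:
            return v.replace(tzinfo=timezone.utc)
        return v.astimezone(timezone.utc)


class ForecastSeries(BaseModel):
    """Ordered 3-hourly forecast covering at least 24 h."""

    samples: list[WeatherSample]

    @model_validator(mode="after")
    def _check_spacing(self) -> "ForecastSeries":
        ts = [s.timestamp for s in self.samples]
        if len(ts) < 2:
            return self
        deltas = {(b - a).total_seconds() for a, b in zip(ts, ts[1:])}
        if any(d <= 0 for d in deltas):
            raise ValueError("timestamps must be strictly increasing")
        if len(deltas) > 1:
            raise ValueError("timestamps must be uniformly spaced")
        return self

    def __iter__(self) -> Iterator[WeatherSample]:  # type: ignore[override]
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> WeatherSample:
        return self.samples[i]


def _cloud_to_octa(value: float, unit: str) -> float:
    if unit == "percent":
        return float(round(value / 12.5))
    return float(value)


def read_forecast(path: str | Path, dialect: str = "owm") -> ForecastSeries:
    """Read a forecast JSON file into a validated :class:`ForecastSeries`.

    The only supported dialect, ``"owm"``, mirrors the OpenWeatherMap
    5-day/3-hour schema: top-level ``city.coord`` with ``lat``/``lon`` and a
    ``list`` of steps, each with ``dt`` (unix UTC), ``main.temp`` (degC),
    ``main.humidity`` (%), ``main.pressure`` (hPa), ``wind.speed`` (m/s, or
    km/h if ``wind.unit == "km/h"``), ``clouds.all`` (% cover) and optional
    ``rain.3h`` (ml) / ``snow.3h`` (cm).
    """
    if dialect != "owm":
        raise ValueError(f"unknown forecast dialect: {dialect!r}")
    raw = json.loads(Path(path).read_text())
    try:
        coord = raw["city"]["coord"]
        lat, lon = float(coord["lat"]), float(coord["lon"])
        steps = raw["list"]
    except KeyError as exc:  # pragma: no cover - message matters, not branch
        raise ValueError(f"forecast file missing mandatory field: {exc}") from exc

    samples = []
    for step in steps:
        try:
            main = step["main"]
            wind = step["wind"]
            speed = float(wind["speed"])
            if wind.get("unit") == "km/h":
                speed /= 3.6
            samples.append(
                WeatherSample(
                    t_air=float(main["temp"]),
                    rh=float(main["humidity"]),
                    p_air=float(main["pressure"]) / 10.0,  # hPa -> kPa
                    v10=speed,
                    cloud=_cloud_to_octa(float(step["clouds"]["all"]), "percent"),
                    rain=float(step.get("rain", {}).get("3h", 0.0)),
                    snow=float(step.get("snow", {}).get("3h", 0.0)),
                    lat=lat,
                    lon=lon,
                    timestamp=datetime.fromtimestamp(int(step["dt"]), tz=timezone.utc),
                )
            )
        except KeyError as exc:
            raise ValueError(f"forecast step missing mandatory field: {exc}") from exc
    return ForecastSeries(samples=samples)


def write_forecast(series: ForecastSeries, path: str | Path) -> None:
    """Write a series back out in the same JSON dialect read_forecast accepts."""
    if not len(series):
        raise ValueError("cannot write an empty series")
    first = series[0]
    payload = {
        "city": {"coord": {"lat": first.lat, "lon": first.lon}},
        "list": [
            {
                "dt": int(s.timestamp.timestamp()),
                "main": {
                    "temp": s.t_air,
                    "humidity": s.rh,
                    "pressure": s.p_air * 10.0,
                },
                "wind": {"speed": s.v10},
                "clouds": {"all": s.cloud * 12.5},
                "rain": {"3h": s.rain},
                "snow": {"3h": s.snow},
            }
            for s in series
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# --- synthetic scenarios ---------------------------------------------------
#
# Each scenario fixes a site, a season and diurnal envelopes for the raw
# fields.  Envelope midpoints/amplitudes are chosen so the series look like
# plausible 3 h forecasts for that climate; small seeded jitter is added but
# always clipped back inside the scenario's stated temperature span.

_SCENARIOS: dict[str, dict] = {
    # Mediterranean heat episode: 28-38 degC, dry, mostly clear.
    "heatwave": dict(
        lat=37.98, lon=23.73, start="2021-07-15T00:00:00+00:00",
        t_mid=33.0, t_amp=4.5, t_jitter=0.4, rh_mid=35.0, rh_amp=10.0,
        v_mid=2.5, v_amp=1.5, cloud_mean=1.0, p_air=101.0,
        t_lo=28.0, t_hi=38.0,
    ),
    # High-latitude winter: -25..-5 degC, windy, overcast, polar night.
    "arctic": dict(
        lat=69.65, lon=18.96, start="2021-01-20T00:00:00+00:00",
        t_mid=-15.0, t_amp=8.0, t_jitter=1.0, rh_mid=75.0, rh_amp=10.0,
        v_mid=6.0, v_amp=3.0, cloud_mean=6.0, p_air=100.2,
        t_lo=-25.0, t_hi=-5.0,
    ),
    # North-European shoulder season: mild, breezy, half-covered sky.
    "temperate": dict(
        lat=55.68, lon=12.57, start="2021-05-10T00:00:00+00:00",
        t_mid=12.0, t_amp=3.5, t_jitter=0.5, rh_mid=65.0, rh_amp=10.0,
        v_mid=4.0, v_amp=2.0, cloud_mean=4.0, p_air=101.3,
        t_lo=4.0, t_hi=20.0,
    ),
    # Clear-sky sinusoid with solar-consistent phase (max ~2 h after local
    # solar noon), for exercising the radiation chain.
    "diurnal-cycle": dict(
        lat=40.0, lon=0.0, start="2021-06-21T00:00:00+00:00",
        t_mid=22.0, t_amp=6.0, t_jitter=0.0, rh_mid=50.0, rh_amp=5.0,
        v_mid=2.0, v_amp=0.5, cloud_mean=0.0, p_air=101.3,
        t_lo=10.0, t_hi=34.0,
    ),
}

SCENARIOS = tuple(_SCENARIOS)


def generate_synthetic_forecast(
    seed: int,
    scenario: str,
    params: dict | None = None,
    n_samples: int = 9,
) -> ForecastSeries:
    """Generate a deterministic 3-hourly synthetic forecast.

    ``params`` overrides either scenario envelope keys (``lat``, ``lon``,
    ``p_air`` ...) or forces a raw field to a constant for every sample
    (``t_air``, ``rh``, ``v10``, ``cloud``).  Nine samples at 3 h spacing
    cover a full 24 h window.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(_SCENARIOS)}"
        )
    cfg = dict(_SCENARIOS[scenario])
    params = dict(params or {})
    forced = {k: params.pop(k) for k in ("t_air", "rh", "v10", "cloud") if k in params}
    unknown = set(params) - set(cfg)
    if unknown:
        raise ValueError(f"unknown scenario override(s): {sorted(unknown)}")
    cfg.update(params)

    rng = np.random.default_rng(seed)
    start = datetime.fromisoformat(cfg["start"])
    # Diurnal phase: temperature peaks ~2 h after local solar noon.
    solar_noon_utc_h = 12.0 - cfg["lon"] / 15.0

    samples = []
    for i in range(n_samples):
        ts = start + timedelta(hours=3 * i)
        hour_utc = ts.hour + ts.minute / 60.0
        phase = 2.0 * math.pi * (hour_utc - (solar_noon_utc_h + 2.0)) / 24.0
        t = cfg["t_mid"] + cfg["t_amp"] * math.cos(phase)
        t += rng.normal(0.0, cfg["t_jitter"]) if cfg["t_jitter"] else 0.0
        t = min(max(t, cfg["t_lo"]), cfg["t_hi"])
        rh = cfg["rh_mid"] - cfg["rh_amp"] * math.cos(phase) + rng.normal(0.0, 2.0)
        rh = min(max(rh, 5.0), 100.0)
        v = max(0.0, cfg["v_mid"] + cfg["v_amp"] * math.sin(phase) + rng.normal(0.0, 0.3))
        cloud = float(np.clip(round(cfg["cloud_mean"] + rng.normal(0.0, 1.0)), 0, 8))
        if cfg["cloud_mean"] == 0.0:
            cloud = 0.0
        samples.append(
            WeatherSample(
                t_air=forced.get("t_air", t),
                rh=forced.get("rh", rh),
                p_air=cfg["p_air"],
                v10=forced.get("v10", v),
                cloud=forced.get("cloud", cloud),
                rain=0.0,
                snow=0.0,
                lat=cfg["lat"],
                lon=cfg["lon"],
                timestamp=ts,
            )
        )
    return ForecastSeries(samples=samples)
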