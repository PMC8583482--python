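"""Per-sample orchestration: mode dispatch, index, notifications, forecasts.

For each weather sample the engine runs the heat screening with the
worst-case (cloud-unattenuated) solar load and, if the Heat Risk Level stays
below the alert band, falls back to the cold assessment computed with forced
full overcast (8 octa) - both worst-case policies by design.  Indoor mode
bypasses the weather-driven paths entirely and uses PMV.  The resulting
thermal stress index is always clamped to [-4, +4].

Notifications are emitted as codes from a documented catalogue; the message
text is a pure presentation concern keyed by code + profile, so caregiver
profiles change the advice wording but never the index.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import cold as cold_mod
from . import heat as heat_mod
from .globe import GlobeSet, globe_set, mean_radiant_temperature
from .indoor import IndoorAssessment, IndoorEnvironment, pmv_ppd
from .meteo import cloud_transmittance, derive, saturation_vapour_pressure, vapour_pressure
from .person import (
    ActivityProfile,
    ClothingEnsemble,
    PersonProfile,
    activity_profile,
    clothing_catalogue,
)
from .phs import PhsResult, run_phs
from .weather_io import ForecastSeries, WeatherSample

__all__ = [
    "PersonContext",
    "EngineSettings",
    "Assessment",
    "NotificationCode",
    "NOTIFICATION_CATALOGUE",
    "load_context",
    "assess",
    "decision_tree",
    "forecast_indices",
    "flag_windows",
    "sensitivity_grid",
]

_INDEX_MIN, _INDEX_MAX = -4.0, 4.0
_ACTIVITY_ORDER = ["rest", "low", "moderate", "high", "very-high"]


@dataclass(frozen=True)
class PersonContext:
    """Bundle of everything personal: body, activity, clothing, indoor state."""

    person: PersonProfile
    activity: ActivityProfile
    clothing: ClothingEnsemble
    indoor: IndoorEnvironment | None = None
    perception: int | None = None  # -3..+3 self-reported sensation, echo only


@dataclass(frozen=True)
class EngineSettings:
    """Engine policy knobs.

    ``heat_handover_hrl`` is the HRL at which the engine switches from the
    (stretched) cold assessment to heat mode - the first WBGT alert band by
    default.  The fan/cooling-vest advice gates are activity levels.
    """

    heat_handover_hrl: float = 0.8
    phs_duration_min: int = 480
    fan_max_activity: str = "moderate"  # fans help up to this level
    vest_min_activity: str = "high"  # cooling vests from this level up


@dataclass(frozen=True)
class NotificationCode:
    code: str
    params: dict = field(default_factory=dict)
    audience: str = "personal"


# code -> short description (presentation layers key message text on
# code + language + profile; computation emits codes only)
NOTIFICATION_CATALOGUE: dict[str, str] = {
    "heat.alert_approaching": "effective WBGT is approaching the reference alert limit",
    "heat.adjust_clothing": "lighter clothing would lower heat stress (CAV > 0)",
    "heat.reschedule_work": "rescheduling heavy work avoids peak heat stress",
    "heat.hydrate": "remember regular rehydration",
    "heat.use_fan": "fans aid evaporative cooling at this activity level",
    "heat.cooling_vest": "consider a cooling vest at high activity",
    "heat.exposure_limit": "limited exposure duration before core temperature rises",
    "cold.wind_stopper": "wind-stopping outer layer advised (strong windchill)",
    "cold.frostbite_risk": "windchill below freezing: protect exposed skin",
    "cold.underdressed_dle": "worn insulation below minimal requirement; exposure limited",
    "cold.overdressed_sweat": "overdressed: avoid sweating in the cold",
    "indoor.too_warm": "indoor environment warm; ventilate or reduce heating",
    "indoor.too_cold": "indoor environment cool; add clothing or heating",
    "perception.sensitivity": "self-reported perception deviates from the rational index",
}


@dataclass(frozen=True)
class Assessment:
    """Result for one sample: mode, index, sub-model outputs, notifications."""

    mode: str  # heat / cold / indoor
    index: float  # clamped to [-4, +4]
    weather: WeatherSample | None = None
    heat: heat_mod.HeatAssessment | None = None
    cold: cold_mod.ColdAssessment | None = None
    indoor: IndoorAssessment | None = None
    phs: PhsResult | None = None
    globes: GlobeSet | None = None
    notifications: tuple[NotificationCode, ...] = ()


def _clamp(x: float) -> float:
    return max(_INDEX_MIN, min(_INDEX_MAX, x))


def load_context(path: str) -> tuple[PersonContext, EngineSettings]:
    """Load person + context + engine settings from a TOML config file.

    Recognised tables: ``[person]`` (age, height, weight, sex, acclimatised,
    profile), ``[activity]`` (level), ``[clothing]`` (name and/or icl, im_st,
    p_air_perm), optional ``[indoor]`` (enabled, t_air, rh, windows_open,
    thermostat) and optional ``[engine]`` overrides.
    """
    if sys.version_info >= (3, 11):
        import tomllib
    else:  # pragma: no cover
        import tomli as tomllib
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)

    person = PersonProfile(**cfg["person"])
    activity = activity_profile(cfg.get("activity", {}).get("level", "moderate"), person)
    cl = dict(cfg.get("clothing", {"name": "casual"}))
    clothing = clothing_catalogue(cl.pop("name", "custom"), **cl)
    indoor = None
    ind_cfg = dict(cfg.get("indoor", {}))
    if ind_cfg.pop("enabled", False):
        indoor = IndoorEnvironment(
            t_air_indoor=ind_cfg["t_air"],
            rh_indoor=ind_cfg.get("rh", 50.0),
            windows_open=ind_cfg.get("windows_open", False),
            thermostat=ind_cfg.get("thermostat", 3),
        )
    perception = cfg.get("perception", {}).get("sensation")
    context = PersonContext(
        person=person,
        activity=activity,
        clothing=clothing,
        indoor=indoor,
        perception=perception,
    )
    return context, EngineSettings(**cfg.get("engine", {}))


def assess(
    sample: WeatherSample,
    context: PersonContext,
    settings: EngineSettings = EngineSettings(),
) -> Assessment:
    """Assess one weather sample (or the indoor state) for one person."""
    if context.indoor is not None:
        ind = pmv_ppd(context.indoor, context.activity.q_met_wm2, context.clothing.icl)
        assessment = Assessment(
            mode="indoor",
            index=_clamp(ind.index),
            weather=sample,
            indoor=ind,
        )
        return _with_notifications(assessment, context, settings)

    met = derive(sample)
    # Heat path: worst case, no cloud attenuation of the solar load.
    globes = globe_set(
        t_air=sample.t_air,
        rh=sample.rh,
        v2=met.v2,
        p_air=sample.p_air,
        q_solar=met.q_solar,
        cza=met.geometry.cza,
        transmittance=cloud_transmittance(sample.cloud),
    )
    heat = heat_mod.assess_heat(globes.wbgt, context.clothing, context.activity, context.person)

    t_wc = cold_mod.windchill(sample.t_air, sample.v10)

    if heat.hrl >= settings.heat_handover_hrl:
        phs = None
        if 15.0 <= sample.t_air <= 50.0:
            phs = run_phs(
                t_air=sample.t_air,
                t_mr=globes.t_mr,
                pv_air=met.pv_air,
                v2=met.v2,
                q_met_wm2=context.activity.q_met_wm2,
                clothing=context.clothing,
                person=context.person,
                duration_min=settings.phs_duration_min,
                v_walk=context.activity.v_walk,
            )
        assessment = Assessment(
            mode="heat",
            index=_clamp(heat.index),
            weather=sample,
            heat=heat,
            phs=phs,
            globes=globes,
        )
        return _with_notifications(assessment, context, settings)

    # Cold path: worst case, forced full overcast (8 octa) for the radiant load.
    q_cold = met.q_solar * cloud_transmittance(8.0)
    from .globe import globe_temperature  # local alias keeps module surface tidy

    t_g_cold = globe_temperature(
        sample.t_air, met.v2, q_cold, sample.p_air, cza=met.geometry.cza, rh=sample.rh
    )
    t_mr_cold = mean_radiant_temperature(t_g_cold, sample.t_air, met.v2)
    ireq = cold_mod.run_ireq(
        t_air=sample.t_air,
        t_mr=t_mr_cold,
        rh=sample.rh,
        v2=met.v2,
        q_met_wm2=context.activity.q_met_wm2,
        clothing=context.clothing,
        v_walk=context.activity.v_walk,
    )
    idx = cold_mod.cold_index(
        context.clothing.icl / 0.155, ireq.icl_neutral, ireq.icl_minimal
    )
    cold = cold_mod.ColdAssessment(
        icl_neutral=ireq.icl_neutral,
        icl_minimal=ireq.icl_minimal,
        dle_cold=ireq.dle_cold,
        t_windchill=t_wc,
        index=_clamp(idx),
        frostbite_flag=t_wc < 0.0,
    )
    assessment = Assessment(
        mode="cold",
        index=cold.index,
        weather=sample,
        cold=cold,
        globes=globes,
    )
    return _with_notifications(assessment, context, settings)


def decision_tree(
    assessment: Assessment,
    context: PersonContext,
    settings: EngineSettings = EngineSettings(),
) -> list[NotificationCode]:
    """Derive the ordered notification codes for an assessment.

    Heat side: alert-approach note inside the 0.8..1.0 HRL band, a clothing
    tip only when CAV > 0, rescheduling only above moderate activity,
    hydration always, fan/cooling-vest tips gated on activity level.  Cold
    side: wind-stopper when windchill is at least 2 degC below air
    temperature, frostbite notice when windchill is below 0 degC,
    underdressed -> exposure-limit minutes, overdressed -> sweat prevention.
    """
    out: list[NotificationCode] = []
    audience = context.person.profile
    act_rank = _ACTIVITY_ORDER.index(context.activity.level)

    def emit(code: str, **params: float) -> None:
        out.append(NotificationCode(code=code, params=params, audience=audience))

    if assessment.mode == "heat" and assessment.heat is not None:
        h = assessment.heat
        if 0.8 < h.hrl < 1.0:
            emit("heat.alert_approaching", hrl=h.hrl)
        if h.cav > 0.0:
            emit("heat.adjust_clothing", cav=h.cav)
        if act_rank > _ACTIVITY_ORDER.index("moderate"):
            emit("heat.reschedule_work")
        emit("heat.hydrate")
        if act_rank <= _ACTIVITY_ORDER.index(settings.fan_max_activity):
            emit("heat.use_fan")
        if act_rank >= _ACTIVITY_ORDER.index(settings.vest_min_activity):
            emit("heat.cooling_vest")
        if assessment.phs is not None and assessment.phs.dle_hot < settings.phs_duration_min:
            emit("heat.exposure_limit", minutes=assessment.phs.dle_hot)

    if assessment.mode == "cold" and assessment.cold is not None:
        c = assessment.cold
        t_air = assessment.weather.t_air if assessment.weather else 0.0
        if c.t_windchill <= t_air - 2.0:
            emit("cold.wind_stopper", t_windchill=c.t_windchill)
        if c.frostbite_flag:
            emit("cold.frostbite_risk", t_windchill=c.t_windchill)
        user_clo = context.clothing.icl / 0.155
        if user_clo < c.icl_minimal:
            emit("cold.underdressed_dle", minutes=c.dle_cold or 0.0)
        elif user_clo > c.icl_neutral:
            emit("cold.overdressed_sweat")

    if assessment.mode == "indoor" and assessment.indoor is not None:
        if assessment.indoor.pmv > 1.0:
            emit("indoor.too_warm", pmv=assessment.indoor.pmv)
        elif assessment.indoor.pmv < -1.0:
            emit("indoor.too_cold", pmv=assessment.indoor.pmv)

    if context.perception is not None and abs(context.perception - assessment.index) >= 2.0:
        emit("perception.sensitivity", perception=context.perception)
    return out


def _with_notifications(
    assessment: Assessment, context: PersonContext, settings: EngineSettings
) -> Assessment:
    notes = tuple(decision_tree(assessment, context, settings))
    return Assessment(**{**assessment.__dict__, "notifications": notes})


def forecast_indices(
    series: ForecastSeries,
    context: PersonContext,
    settings: EngineSettings = EngineSettings(),
) -> tuple[list[Assessment], list[dict]]:
    """Assess every 3 h sample and flag high-stress windows (|index| > 2)."""
    assessments = [assess(s, context, settings) for s in series]
    return assessments, flag_windows(assessments)


def flag_windows(assessments: Sequence[Assessment]) -> list[dict]:
    """Contiguous runs where the index magnitude exceeds 2."""
    windows: list[dict] = []
    current: dict | None = None
    for a in assessments:
        ts = a.weather.timestamp if a.weather else None
        if abs(a.index) > 2.0:
            if current is None:
                current = {"start": ts, "end": ts, "peak_index": a.index}
            else:
                current["end"] = ts
                if abs(a.index) > abs(current["peak_index"]):
                    current["peak_index"] = a.index
        elif current is not None:
            windows.append(current)
            current = None
    if current is not None:
        windows.append(current)
    return windows


def sensitivity_grid(
    t_air_range: Sequence[float],
    activities: Sequence[str],
    clothing: ClothingEnsemble,
    acclimatised: bool,
    v10: float = 1.0,
    settings: EngineSettings = EngineSettings(),
) -> pd.DataFrame:
    """Index over an air-temperature x activity grid at fixed humidity load.

    The vapour pressure is pinned to that of 20 degC / 50% RH at every air
    temperature (RH capped at 100% when the air is too cold to hold it),
    wind is 1 m/s, there is no solar radiation, and the reference person is
    1.80 m / 80 kg.  Returns a tidy frame with columns ``t_air``,
    ``activity``, ``index``, ``mode``.
    """
    pv_fixed = vapour_pressure(20.0, 50.0)
    person = PersonProfile(
        age=35, height=180.0, weight=80.0, sex="male", acclimatised=acclimatised
    )
    rows = []
    for level in activities:
        activity = activity_profile(level, person)
        for t_air in t_air_range:
            rh = min(100.0, 100.0 * pv_fixed / saturation_vapour_pressure(t_air))
            v2 = v10 * (0.2**0.25)
            globes = globe_set(t_air, rh, v2, 101.3, q_solar=0.0)
            heat = heat_mod.assess_heat(globes.wbgt, clothing, activity, person)
            if heat.hrl >= settings.heat_handover_hrl:
                mode, idx = "heat", heat.index
            else:
                ireq = cold_mod.run_ireq(
                    t_air, globes.t_mr, rh, v2, activity.q_met_wm2, clothing,
                    v_walk=activity.v_walk,
                )
                idx = cold_mod.cold_index(
                    clothing.icl / 0.155, ireq.icl_neutral, ireq.icl_minimal
                )
                mode = "cold"
            rows.append(
                {"t_air": t_air, "activity": level, "index": _clamp(idx), "mode": mode}
            )
    return pd.DataFrame(rows)
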