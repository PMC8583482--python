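"""Indoor mode: Fanger PMV/PPD with the app-style indoor defaults.

Indoors the mean radiant temperature is taken equal to air temperature and
air speed is 0.2 m/s with windows closed or 0.5 m/s with windows open.  The
indoor thermal stress index equals the PMV.  A configurable adaptive
relation suggests an indoor temperature (and, through the outdoor vapour
pressure, a humidity) - purely advisory, the assessment always uses the
user-entered values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, Field, model_validator

from .meteo import suggested_indoor_rh, vapour_pressure
from .weather_io import WeatherSample

__all__ = [
    "IndoorEnvironment",
    "IndoorAssessment",
    "ppd_from_pmv",
    "pmv_ppd",
    "suggested_indoor_temperature",
    "suggest_indoor_environment",
]

_V_WINDOWS_CLOSED = 0.2
_V_WINDOWS_OPEN = 0.5

# adaptive suggestion defaults: t = slope * t_out + offset, then +/- step per
# thermostat notch from the neutral setting 3; clamped to a sane band
_ADAPTIVE_SLOPE = 0.33
_ADAPTIVE_OFFSET = 18.8
_THERMOSTAT_STEP = 1.0
_SUGGEST_MIN, _SUGGEST_MAX = 16.0, 30.0


class IndoorEnvironment(BaseModel):
    """User-entered indoor conditions; radiant temperature equals air."""

    t_air_indoor: float
    rh_indoor: float = Field(ge=0.0, le=100.0)
    windows_open: bool = False
    thermostat: int = Field(default=3, ge=1, le=5)
    v_air_indoor: float | None = None  # defaulted from the window state

    @model_validator(mode="after")
    def _default_air_speed(self) -> "IndoorEnvironment":
        if self.v_air_indoor is None:
            object.__setattr__(
                self,
                "v_air_indoor",
                _V_WINDOWS_OPEN if self.windows_open else _V_WINDOWS_CLOSED,
            )
        return self

    @property
    def t_mr_indoor(self) -> float:
        return self.t_air_indoor


@dataclass(frozen=True)
class IndoorAssessment:
    pmv: float
    ppd: float  # % dissatisfied, >= 5
    index: float  # equals pmv
    warnings: tuple[str, ...] = ()


def ppd_from_pmv(pmv: float) -> float:
    """Predicted percentage dissatisfied: 100 - 95 exp(-0.03353 pmv^4 - 0.2179 pmv^2)."""
    return 100.0 - 95.0 * math.exp(-0.03353 * pmv**4 - 0.2179 * pmv**2)


def pmv_ppd(env: IndoorEnvironment, q_met_wm2: float, icl: float) -> IndoorAssessment:
    """Fanger PMV/PPD (ISO 7730) for the indoor environment.

    ``q_met_wm2`` in W/m2, ``icl`` in m2 K/W.  The clothing surface
    temperature is solved by damped iteration to 1e-5 degC with the
    natural/forced convective coefficient branch taken at each step.
    """
    ta = env.t_air_indoor
    tr = env.t_mr_indoor
    vel = float(env.v_air_indoor or _V_WINDOWS_CLOSED)
    pa = vapour_pressure(ta, env.rh_indoor) * 1000.0  # Pa

    m = q_met_wm2
    w = 0.0
    icl_clo = icl / 0.155
    fcl = 1.0 + 1.29 * icl if icl <= 0.078 else 1.05 + 0.645 * icl

    warnings = []
    if not (10.0 <= ta <= 30.0 and m / 58.15 <= 4.0 and vel <= 1.0):
        warnings.append("inputs outside the nominal PMV validity envelope")
    if not 0.0 <= icl_clo <= 2.0:
        warnings.append(f"clothing {icl_clo:.2f} Clo outside PMV envelope 0..2")

    mw = m - w
    tcl = ta + (35.5 - ta) / (3.5 * (6.45 * icl + 0.1))  # standard initial guess
    hc = 12.1 * math.sqrt(vel)
    for _ in range(300):
        hc_forced = 12.1 * math.sqrt(vel)
        hc_natural = 2.38 * abs(tcl - ta) ** 0.25
        hc = max(hc_forced, hc_natural)
        rad = 3.96e-8 * fcl * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4)
        conv = fcl * hc * (tcl - ta)
        tcl_new = 35.7 - 0.028 * mw - icl * (rad + conv)
        if abs(tcl_new - tcl) < 1e-5:
            tcl = tcl_new
            break
        tcl = 0.5 * (tcl + tcl_new)

    rad = 3.96e-8 * fcl * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4)
    conv = fcl * hc * (tcl - ta)
    load = (
        mw
        - 3.05e-3 * (5733.0 - 6.99 * mw - pa)
        - 0.42 * (mw - 58.15)
        - 1.7e-5 * m * (5867.0 - pa)
        - 0.0014 * m * (34.0 - ta)
        - rad
        - conv
    )
    pmv = (0.303 * math.exp(-0.036 * m) + 0.028) * load
    return IndoorAssessment(pmv=pmv, ppd=ppd_from_pmv(pmv), index=pmv, warnings=tuple(warnings))


def suggested_indoor_temperature(
    outdoor: WeatherSample, thermostat: int = 3, windows_open: bool = False
) -> float:
    """Advisory indoor temperature suggestion from the outdoor conditions.

    A linear adaptive-comfort relation on outdoor temperature, shifted by
    one degree per thermostat notch away from the neutral setting 3.  The
    window state does not move the temperature suggestion (it sets the
    indoor air speed).  Only user-entered values ever feed the assessment.
    """
    if not 1 <= thermostat <= 5:
        raise ValueError("thermostat setting must be 1..5")
    t = _ADAPTIVE_SLOPE * outdoor.t_air + _ADAPTIVE_OFFSET
    t += _THERMOSTAT_STEP * (thermostat - 3)
    return min(max(t, _SUGGEST_MIN), _SUGGEST_MAX)


def suggest_indoor_environment(
    outdoor: WeatherSample, thermostat: int = 3, windows_open: bool = False
) -> IndoorEnvironment:
    """Suggested indoor environment (temperature + matching RH) for a sample."""
    t_suggest = suggested_indoor_temperature(outdoor, thermostat, windows_open)
    pv_out = vapour_pressure(outdoor.t_air, outdoor.rh)
    return IndoorEnvironment(
        t_air_indoor=t_suggest,
        rh_indoor=suggested_indoor_rh(t_suggest, pv_out),
        windows_open=windows_open,
        thermostat=thermostat,
    )
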