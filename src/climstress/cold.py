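"""Cold path: windchill, required clothing insulation (IREQ) and cold index.

IREQ (ISO 11079) solves the whole-body heat balance

    M - W = E_res + C_res + E + R + C + S

for the clothing insulation that closes it (S = 0) at two physiological
criteria: *neutral* (mean skin temperature and sweating at the thermoneutral
level, sustainable for a full shift) and *minimal* (cooled skin, no
thermoregulatory sweating, the least insulation that still limits strain).
Convection and radiation pass through the clothing area factor, the
evaporative path uses a Lewis-type relation with a fixed ensemble
permeability index of 0.38, and respiratory losses follow the standard
expired-air regressions.  The required *resultant* insulation is converted
to the basic (static) insulation a user can compare with a catalogue value
through a wind/body-motion reduction factor scaled by the ensemble's air
permeability.

When the worn insulation is below the minimal requirement, the duration
limited exposure DLE_cold follows from the permissible body heat debt
(40 Wh/m2) over the net cooling rate.

The windchill index is the JAG/TI-style regression on air temperature and
10 m wind speed; below the formula's validity floor (1.34 m/s) it returns
the air temperature unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .person import ClothingEnsemble, si_to_clo

__all__ = [
    "ColdAssessment",
    "IreqResult",
    "windchill",
    "run_ireq",
    "cold_index",
]

_SIGMA = 5.67e-8
_EMIS = 0.95
_AR_ADU = 0.77  # radiating area fraction, standing
_Q_LIM_WH_M2 = 40.0  # permissible body heat debt
_WINDCHILL_FLOOR = 1.34  # m/s, ~4.8 km/h
_INDEX_MIN = -4.0


@dataclass(frozen=True)
class IreqResult:
    icl_neutral: float  # Clo, required basic insulation, neutral criterion
    icl_minimal: float  # Clo, required basic insulation, minimal criterion
    dle_cold: float | None  # minutes when underdressed, else None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ColdAssessment:
    icl_neutral: float
    icl_minimal: float
    dle_cold: float | None
    t_windchill: float
    index: float
    frostbite_flag: bool


def windchill(t_air: float, v10: float) -> float:
    """Windchill temperature (degC) from air temperature and 10 m wind (m/s).

    13.12 + 0.6215 T + (0.3965 T - 11.37) v^0.16; the 0.16 exponent also
    stands in for the 10 m -> 2 m wind scaling, so the 10 m speed is used
    directly.  Below 1.34 m/s the regression is outside its domain and the
    air temperature is returned.
    """
    if v10 < 0.0:
        raise ValueError("wind speed must be non-negative")
    if v10 < _WINDCHILL_FLOOR:
        return t_air
    vp = v10**0.16
    return 13.12 + 0.6215 * t_air - 11.37 * vp + 0.3965 * t_air * vp


def _p_sat_kpa(t: float) -> float:
    return 0.6105 * math.exp(17.27 * t / (t + 237.3))


def _insulation_reduction(var: float, walk: float, p_air_perm: float) -> float:
    """Wind/body-motion reduction of total insulation, scaled by air permeability.

    Nilsson/ISO 9920 style: exp([-0.0512 (v-0.4) + 0.000794 (v-0.4)^2
    - 0.0639 w] * p^0.144), clipped to (0, 1].
    """
    v = max(var - 0.4, 0.0)
    base = -0.0512 * v + 0.000794 * v**2 - 0.0639 * walk
    return min(1.0, math.exp(base * p_air_perm**0.144))


def _dry_balance_tcl(
    i_clr: float, t_sk: float, q_dry: float, t_air: float, t_mr: float, hc: float
) -> tuple[float, float, float]:
    """Clothing surface temperature consistent with conduction through i_clr."""
    t_cl = t_sk - i_clr * q_dry
    fcl = 1.0 + 1.197 * i_clr
    tm = (t_cl + t_mr) / 2.0 + 273.15
    hr = _EMIS * _SIGMA * _AR_ADU * 4.0 * tm**3
    return t_cl, fcl, hr


def _solve_required(
    t_sk: float,
    wet: float,
    m: float,
    t_air: float,
    t_mr: float,
    pa: float,
    hc: float,
    e_res: float,
    c_res: float,
) -> float:
    """Required resultant clothing insulation (m2 K/W) closing the balance."""
    p_sks = _p_sat_kpa(t_sk)
    i_clr = 0.155
    for _ in range(200):
        fcl = 1.0 + 1.197 * i_clr
        r_t = (0.06 / 0.38) * (0.085 / fcl + i_clr)
        e = wet * (p_sks - pa) / r_t
        q_dry = m - e_res - c_res - e
        if q_dry <= 0.0:
            return 0.0
        t_cl, fcl, hr = _dry_balance_tcl(i_clr, t_sk, q_dry, t_air, t_mr, hc)
        t_cl_star = (q_dry / fcl + hr * t_mr + hc * t_air) / (hr + hc)
        i_new = max(0.0, (t_sk - t_cl_star) / q_dry)
        if abs(i_new - i_clr) < 1e-5:
            return i_new
        i_clr = 0.7 * i_clr + 0.3 * i_new
    raise RuntimeError("IREQ insulation solve did not converge")


def _storage_rate(
    i_clr_user: float,
    t_sk: float,
    wet: float,
    m: float,
    t_air: float,
    t_mr: float,
    pa: float,
    hc: float,
    e_res: float,
    c_res: float,
) -> float:
    """Heat storage rate S (W/m2, negative = cooling) at the worn insulation."""
    p_sks = _p_sat_kpa(t_sk)
    fcl = 1.0 + 1.197 * i_clr_user
    r_t = (0.06 / 0.38) * (0.085 / fcl + i_clr_user)
    e = wet * (p_sks - pa) / r_t
    t_cl = t_sk  # iterate clothing surface against dry loss
    for _ in range(200):
        tm = (t_cl + t_mr) / 2.0 + 273.15
        hr = _EMIS * _SIGMA * _AR_ADU * 4.0 * tm**3
        # conduction through clothing equals surface dry loss
        t_cl_new = ((t_sk / max(i_clr_user, 1e-4)) + fcl * (hr * t_mr + hc * t_air)) / (
            1.0 / max(i_clr_user, 1e-4) + fcl * (hr + hc)
        )
        if abs(t_cl_new - t_cl) < 1e-5:
            t_cl = t_cl_new
            break
        t_cl = 0.5 * t_cl + 0.5 * t_cl_new
    dry = fcl * (hr * (t_cl - t_mr) + hc * (t_cl - t_air))
    return m - e_res - c_res - e - dry


def run_ireq(
    t_air: float,
    t_mr: float,
    rh: float,
    v2: float,
    q_met_wm2: float,
    clothing: ClothingEnsemble,
    v_walk: float = 0.8,
) -> IreqResult:
    """Required insulation (neutral/minimal, Clo) and cold-exposure limit.

    ``q_met_wm2`` is clipped into the model's 58..290 W/m2 validity band
    (with a warning); wind is floored at 0.4 m/s.  DLE_cold is returned only
    when the worn ensemble provides less than the minimal requirement.
    """
    warnings: list[str] = []
    m = q_met_wm2
    if not 58.0 <= m <= 290.0:
        warnings.append(f"metabolic rate {m:.0f} W/m2 clipped into IREQ band 58..290")
        m = min(max(m, 58.0), 290.0)
    if t_air > 10.0:
        warnings.append(f"t_air={t_air:.1f} degC above the nominal IREQ domain (<= 10)")

    var = min(max(v2, 0.4), 18.0)
    walk = min(max(v_walk, 0.0), 1.2)
    pa = (rh / 100.0) * _p_sat_kpa(t_air)
    hc = 3.5 + 5.2 * var if var < 1.0 else 8.7 * var**0.6

    t_ex = 29.0 + 0.2 * t_air
    p_ex = _p_sat_kpa(t_ex)
    e_res = 0.0173 * m * (p_ex - pa)
    c_res = 0.0014 * m * (t_ex - t_air)

    # neutral: thermoneutral skin, activity-driven sweating
    t_sk_n = 35.7 - 0.0285 * m
    wet_n = min(max(0.001 * m, 0.001), 1.0)
    # minimal: cooled skin, no thermoregulatory sweating
    t_sk_m = 33.34 - 0.0354 * m
    wet_m = 0.06

    i_req_neutral = _solve_required(t_sk_n, wet_n, m, t_air, t_mr, pa, hc, e_res, c_res)
    i_req_minimal = _solve_required(t_sk_m, wet_m, m, t_air, t_mr, pa, hc, e_res, c_res)
    i_req_minimal = min(i_req_minimal, i_req_neutral)

    reduction = _insulation_reduction(var, walk, clothing.p_air_perm)
    icl_neutral_clo = si_to_clo(i_req_neutral / reduction)
    icl_minimal_clo = si_to_clo(i_req_minimal / reduction)

    dle = None
    i_clr_user = clothing.icl * reduction  # worn resultant insulation
    if si_to_clo(clothing.icl) < icl_minimal_clo:
        s = _storage_rate(i_clr_user, t_sk_m, wet_m, m, t_air, t_mr, pa, hc, e_res, c_res)
        if s < 0.0:
            dle = 60.0 * _Q_LIM_WH_M2 / (-s)
    return IreqResult(
        icl_neutral=icl_neutral_clo,
        icl_minimal=icl_minimal_clo,
        dle_cold=dle,
        warnings=tuple(warnings),
    )


def cold_index(icl_user: float, icl_neutral: float, icl_minimal: float) -> float:
    """Map worn vs required insulation (all Clo) onto the cold half of the index.

    Underdressed below the minimal requirement: -1 minus the Clo deficit;
    between minimal and neutral: linear from -1 to 0; overdressed: the Clo
    excess (positive index).  Clamped at -4.
    """
    if icl_user < 0.0:
        raise ValueError("worn insulation must be non-negative")
    if icl_minimal > icl_neutral:
        raise ValueError("minimal required insulation exceeds neutral requirement")
    if icl_user < icl_minimal:
        idx = -1.0 - (icl_minimal - icl_user)
    elif icl_user > icl_neutral:
        idx = icl_user - icl_neutral
    elif icl_neutral == icl_minimal:
        idx = 0.0  # degenerate band: continuous extension
    else:
        idx = -1.0 + (icl_user - icl_minimal) / (icl_neutral - icl_minimal)
    return max(idx, _INDEX_MIN)
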