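"""Heat path: effective WBGT, reference limits, Heat Risk Level and index.

The screening chain follows ISO 7243 as deployed on the HEAT-SHIELD
platform: the measured WBGT is shifted by a clothing adjustment value (CAV)
parameterised on the static evaporative resistance of the worn ensemble,
and compared against an acclimatisation- and metabolism-dependent reference
limit.  The ratio (Heat Risk Level, HRL) maps piecewise-linearly onto the
heat half of the -4..+4 thermal stress index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .person import ActivityProfile, ClothingEnsemble, I_A_STATIC, PersonProfile, si_to_clo

__all__ = [
    "EvapResistance",
    "HeatAssessment",
    "clothing_area_factor",
    "evaporative_resistance",
    "cav",
    "wbgt_ref",
    "heat_index",
    "hrl_category",
    "assess_heat",
]

_FCL_BRANCH_SI = 0.31  # 2 Clo in m2 K/W; linear branch below, power branch above
_INDEX_MAX = 4.0


@dataclass(frozen=True)
class EvapResistance:
    f_cl: float  # clothing area factor, >= 1
    i_t: float  # total insulation, m2 K/W
    re_t_s: float  # static evaporative resistance, m2 kPa/W


@dataclass(frozen=True)
class HeatAssessment:
    wbgt_effective: float  # degC
    cav: float  # degC
    wbgt_ref: float  # degC
    hrl: float  # dimensionless ratio
    category: str  # not-significant / low / moderate / high
    index: float  # heat half of the thermal stress index, >= 0


def clothing_area_factor(icl: float) -> float:
    """Clothing area factor f_cl from basic insulation (m2 K/W).

    Linear 1 + 1.81 Icl below 2 Clo; above, the power form 1.2424 Icl^0.1546
    with insulation expressed in Clo.
    """
    if icl < 0.0:
        raise ValueError("clothing insulation must be non-negative")
    if icl < _FCL_BRANCH_SI:
        return 1.00 + 1.81 * icl
    return 1.2424 * si_to_clo(icl) ** 0.1546


def evaporative_resistance(icl: float) -> EvapResistance:
    """Static evaporative resistance of clothing plus air layer (ISO 9920).

    Total insulation is basic insulation plus the nude air layer reduced by
    the area factor: I_T = Icl + I_a / f_cl; the Lewis-type relation
    R_e,T,s = 0.16 I_T converts to evaporative resistance.
    """
    f_cl = clothing_area_factor(icl)
    i_t = icl + I_A_STATIC / f_cl
    return EvapResistance(f_cl=f_cl, i_t=i_t, re_t_s=0.16 * i_t)


def cav(icl: float) -> float:
    """Clothing adjustment value (degC) added to WBGT for non-reference dress.

    CAV = 5.81 ln(R_e,T,s) + 20.7; zero near the reference cotton ensemble,
    negative for lighter clothing, positive for heavier.
    """
    return 5.81 * math.log(evaporative_resistance(icl).re_t_s) + 20.7


def wbgt_ref(m_watts: float, acclimatised: bool) -> float:
    """WBGT reference (alert) limit in degC for 8 h work at metabolic rate M (W).

    Acclimatised: 56.7 - 11.5 log10(M); unacclimatised: 59.9 - 14.1 log10(M).
    """
    if m_watts <= 0.0:
        raise ValueError("metabolic rate must be positive")
    if acclimatised:
        return 56.7 - 11.5 * math.log10(m_watts)
    return 59.9 - 14.1 * math.log10(m_watts)


def heat_index(hrl: float) -> float:
    """Map the Heat Risk Level ratio onto the heat half of the index.

    Piecewise linear: HRL/0.8 below the alert band, one index unit per 0.2
    of HRL across the low and moderate bands, unit slope above 1.2; clamped
    at +4.
    """
    if hrl < 0.0:
        raise ValueError("heat risk level must be non-negative")
    if hrl < 0.8:
        idx = hrl / 0.8
    elif hrl < 1.0:
        idx = 1.0 + (hrl - 0.8) / 0.2
    elif hrl < 1.2:
        idx = 2.0 + (hrl - 1.0) / 0.2
    else:
        idx = 3.0 + (hrl - 1.2)
    return min(idx, _INDEX_MAX)


def hrl_category(hrl: float) -> str:
    if hrl < 0.8:
        return "not-significant"
    if hrl < 1.0:
        return "low"
    if hrl < 1.2:
        return "moderate"
    return "high"


def assess_heat(
    wbgt: float,
    clothing: ClothingEnsemble,
    activity: ActivityProfile,
    person: PersonProfile,
) -> HeatAssessment:
    """Full heat-path assessment from a (worst-case, unattenuated-sun) WBGT."""
    adjustment = cav(clothing.icl)
    effective = wbgt + adjustment
    ref = wbgt_ref(activity.q_met_w, person.acclimatised)
    hrl = effective / ref
    hrl = max(hrl, 0.0)
    return HeatAssessment(
        wbgt_effective=effective,
        cav=adjustment,
        wbgt_ref=ref,
        hrl=hrl,
        category=hrl_category(hrl),
        index=heat_index(hrl),
    )
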