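"""Predicted Heat Strain (ISO 7933): minute-resolution heat-balance simulation.

The model integrates the body heat balance minute by minute: the required
core temperature follows metabolic rate with a 10 min time constant, skin
temperature relaxes towards a clothed/nude equilibrium regression, dynamic
clothing insulation and evaporative resistance are reduced for wind and
body movement, and the predicted sweat rate chases the required evaporation
under acclimatisation-dependent maxima of wettedness and sweat rate.  The
two outputs used downstream are the duration-limited exposure until rectal
temperature reaches 38 degC and the accumulated sweat loss.

Standing posture, zero external work and a 0.8 m/s walking speed for
non-rest activity are assumed throughout, matching the assessment engine's
person model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .person import ClothingEnsemble, PersonProfile, si_to_clo

__all__ = ["PhsResult", "run_phs"]

_SIGMA = 5.67e-8
_AR_ADU_STANDING = 0.77  # effective radiating area fraction, standing
_FCL_R = 0.97  # emissivity-weighted radiative efficiency of clothing
_LATENT_SWEAT = 2426.0  # J/g, evaporation heat of sweat at the skin


@dataclass
class PhsResult:
    """Outputs of a PHS run.

    ``dle_hot`` is the first minute rectal temperature reaches 38 degC (or
    the full duration if it never does).  ``sweat_total_g`` accumulates over
    the simulated duration; ``sweat_per_hour_g`` normalises it.
    """

    dle_hot: float  # minutes
    sweat_total_g: float
    sweat_per_hour_g: float
    t_rectal_series: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _p_sat_kpa(t: float) -> float:
    return 0.6105 * math.exp(17.27 * t / (t + 237.3))


def _validity_warnings(
    t_air: float, pv_air: float, t_mr: float, v2: float, q_met_wm2: float, icl_clo: float
) -> list[str]:
    checks = [
        (15.0 <= t_air <= 50.0, f"t_air={t_air:.1f} outside 15..50 degC"),
        (0.0 <= pv_air <= 4.5, f"pv_air={pv_air:.2f} outside 0..4.5 kPa"),
        (0.0 <= t_mr - t_air <= 60.0, f"t_mr-t_air={t_mr - t_air:.1f} outside 0..60 degC"),
        (0.0 <= v2 <= 3.0, f"v2={v2:.1f} outside 0..3 m/s"),
        (100.0 <= q_met_wm2 <= 450.0, f"q_met={q_met_wm2:.0f} outside 100..450 W/m2"),
        (0.1 <= icl_clo <= 1.0, f"icl={icl_clo:.2f} outside 0.1..1 Clo"),
    ]
    return [f"outside PHS validity envelope: {msg}" for ok, msg in checks if not ok]


def run_phs(
    t_air: float,
    t_mr: float,
    pv_air: float,
    v2: float,
    q_met_wm2: float,
    clothing: ClothingEnsemble,
    person: PersonProfile,
    duration_min: int = 480,
    v_walk: float = 0.8,
) -> PhsResult:
    """Run the PHS heat-balance simulation.

    ``pv_air`` in kPa, ``q_met_wm2`` in W/m2, 1 min steps up to
    ``duration_min`` (<= 480).  Inputs outside the model's validity envelope
    attach warnings to the result rather than failing - the caller decides.
    """
    if not 0 < duration_min <= 480:
        raise ValueError("duration must be within 1..480 minutes")

    icl_clo = si_to_clo(clothing.icl)
    warnings = _validity_warnings(t_air, pv_air, t_mr, v2, q_met_wm2, icl_clo)

    weight = person.weight
    height_m = person.height / 100.0
    adu = 0.202 * weight**0.425 * height_m**0.725  # Du Bois, SI form
    sp_heat = 57.83 * weight / adu  # body specific heat per m2 skin

    met = q_met_wm2
    work = 0.0
    accl = person.acclimatised

    # dynamic-clothing correction factors (constant over the run)
    v_air = min(v2, 3.0)
    walk = min(v_walk, 1.5)
    var = max(v2, v_walk)  # relative air velocity, walking direction unknown
    cor_cl = min(1.0, 1.044 * math.exp((0.066 * v_air - 0.398) * v_air
                                       + (0.094 * walk - 0.378) * walk))
    cor_ia = min(1.0, math.exp((0.047 * v2 - 0.472) * v2
                               + (0.117 * walk - 0.342) * walk))
    if icl_clo <= 0.6:
        cor_tot = ((0.6 - icl_clo) * cor_ia + icl_clo * cor_cl) / 0.6
    else:
        cor_tot = cor_cl

    fcl = 1.0 + 0.3 * icl_clo
    i_a_st = 0.111  # static boundary-layer insulation, m2 K/W
    i_tot_st = clothing.icl + i_a_st / fcl
    i_tot_dyn = i_tot_st * cor_tot
    i_a_dyn = cor_ia * i_a_st
    i_cl_dyn = i_tot_dyn - i_a_dyn / fcl

    cor_e = (2.6 * cor_tot - 6.5) * cor_tot + 4.9
    im_dyn = min(clothing.im_st * cor_e, 0.9)
    r_t_dyn = i_tot_dyn / im_dyn / 16.7  # dynamic evaporative resistance

    # convective coefficient (dynamic)
    hc_dyn = 3.5 + 5.2 * var if var < 1.0 else 8.7 * var**0.6

    # maximum sweat rate (W/m2) and wettedness
    sw_max = (met - 32.0) * adu
    sw_max = min(max(sw_max, 250.0), 400.0)
    w_max = 1.0 if accl else 0.85
    if accl:
        sw_max *= 1.25

    # state
    t_re = t_cr = t_cr_eq = 36.8
    t_sk = 34.1
    sk_cr_wg = 0.3
    sw_p = 0.0  # predicted sweat rate, W/m2
    sw_tot_wm2_min = 0.0  # accumulated (sweat + respiratory) evaporation, W min/m2
    dle = None
    series = []

    for minute in range(1, duration_min + 1):
        t_sk0, t_re0, t_cr0, t_cr_eq0, wg0 = t_sk, t_re, t_cr, t_cr_eq, sk_cr_wg

        # equilibrium core temperature driven by metabolic rate, tau = 10 min
        t_cr_eq_m = 0.0036 * met + 36.6
        t_cr_eq = t_cr_eq0 * math.exp(-1.0 / 10.0) + t_cr_eq_m * (1.0 - math.exp(-1.0 / 10.0))
        d_stor_eq = sp_heat * (t_cr_eq - t_cr_eq0) * (1.0 - wg0)

        # skin temperature towards clothed/nude equilibrium, tau = 3 min
        t_sk_eq_cl = (12.165 + 0.02017 * t_air + 0.04361 * t_mr + 0.19354 * pv_air
                      - 0.25315 * v2 + 0.005346 * met + 0.51274 * t_re)
        t_sk_eq_nu = (7.191 + 0.064 * t_air + 0.061 * t_mr + 0.198 * pv_air
                      - 0.348 * v2 + 0.616 * t_re)
        if icl_clo >= 0.6:
            t_sk_eq = t_sk_eq_cl
        elif icl_clo <= 0.2:
            t_sk_eq = t_sk_eq_nu
        else:
            t_sk_eq = t_sk_eq_nu + 2.5 * (t_sk_eq_cl - t_sk_eq_nu) * (icl_clo - 0.2)
        t_sk = t_sk0 * math.exp(-1.0 / 3.0) + t_sk_eq * (1.0 - math.exp(-1.0 / 3.0))
        p_sk = _p_sat_kpa(t_sk)

        # respiratory heat losses
        t_exp = 28.56 + 0.115 * t_air + 0.641 * pv_air
        c_res = 0.001516 * met * (t_exp - t_air)
        e_res = 0.00127 * met * (59.34 + 0.53 * t_air - 11.63 * pv_air)

        # clothing surface temperature (radiation linearised each iteration)
        t_cl = t_mr + 0.1
        for _ in range(100):
            t_cl_mean = (t_cl + t_mr) / 2.0 + 273.15
            hr = _FCL_R * _AR_ADU_STANDING * 4.0 * _SIGMA * t_cl_mean**3
            t_cl_new = ((fcl * (hc_dyn * t_air + hr * t_mr) + t_sk / i_cl_dyn)
                        / (fcl * (hc_dyn + hr) + 1.0 / i_cl_dyn))
            if abs(t_cl_new - t_cl) < 1e-4:
                t_cl = t_cl_new
                break
            t_cl = t_cl_new

        conv = fcl * hc_dyn * (t_cl - t_air)
        rad = fcl * hr * (t_cl - t_mr)

        # required evaporation and sweat rate
        e_max = (p_sk - pv_air) / r_t_dyn
        e_req = met - d_stor_eq - work - c_res - e_res - conv - rad

        if e_max <= 0.0:
            # no evaporative cooling possible
            e_p = 0.0
            sw_req = sw_max
        elif e_req <= 0.0:
            e_req = 0.0
            sw_req = 0.0
        else:
            w_req = min(e_req / e_max, 1.7)
            if w_req <= 1.0:
                eff = 1.0 - w_req**2 / 2.0
            else:
                eff = (2.0 - w_req) ** 2 / 2.0
            eff = max(eff, 0.05)
            sw_req = min(e_req / eff, sw_max)

        # predicted sweat rate follows required with tau = 10 min
        sw_p = sw_p * math.exp(-1.0 / 10.0) + sw_req * (1.0 - math.exp(-1.0 / 10.0))
        sw_p = min(sw_p, sw_max)

        if e_max > 0.0:
            k = e_max / sw_p if sw_p > 0.0 else math.inf
            if math.isinf(k):
                w_p = 0.0
            elif k >= 0.5:
                w_p = -k + math.sqrt(k * k + 2.0)
            else:
                w_p = w_max
            w_p = min(w_p, w_max)
            e_p = min(w_p * e_max, sw_p)

        # heat storage and core temperature
        d_storage = e_req - e_p + d_stor_eq
        sk_cr_wg = min(max(0.3 - 0.09 * (t_cr_eq - 36.8), 0.1), 0.3)
        t_cr = ((d_storage / sp_heat + t_sk0 * wg0 / 2.0 - t_sk * sk_cr_wg / 2.0
                 + t_cr0 * (1.0 - wg0 / 2.0)) / (1.0 - sk_cr_wg / 2.0))
        t_re = t_re0 + (2.0 * t_cr - 1.962 * t_re0 - 1.31) / 9.0
        series.append(t_re)

        if dle is None and t_re >= 38.0:
            dle = float(minute)

        sw_tot_wm2_min += sw_p + e_res

    sweat_total_g = sw_tot_wm2_min * adu * 60.0 / _LATENT_SWEAT
    if dle is None:
        dle = float(duration_min)
    return PhsResult(
        dle_hot=dle,
        sweat_total_g=sweat_total_g,
        sweat_per_hour_g=sweat_total_g * 60.0 / duration_min,
        t_rectal_series=series,
        warnings=warnings,
    )
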