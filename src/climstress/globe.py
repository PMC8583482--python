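"""Black-globe, natural wet-bulb, WBGT and mean radiant temperature.

The globe and wick temperatures come from the Liljegren outdoor WBGT model:
each instrument is solved from its own steady-state energy balance
(long-wave + solar gain against convective - and, for the wick, evaporative -
loss) with convection from standard sphere/cylinder Nusselt correlations and
the direct-beam fraction parameterised from the ratio of surface to
top-of-atmosphere irradiance.  A damped fixed-point iteration (damping 0.9,
tolerance 0.02 degC, max 100 iterations) mirrors reference-implementation
practice for these balances.

WBGT is the ISO 7243 weighted sum 0.7 Tnwb + 0.2 Tg + 0.1 Tair.  Mean
radiant temperature inverts the globe-thermometer reading with a convective
coefficient that takes the larger of the natural- and forced-convection
branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GlobeSet",
    "globe_temperature",
    "natural_wet_bulb",
    "wbgt",
    "mean_radiant_temperature",
    "direct_beam_fraction",
    "globe_set",
    "GlobeConvergenceError",
]

# physical constants / instrument geometry (5 cm globe, standard wick)
_SIGMA = 5.6696e-8  # W m-2 K-4
_D_GLOBE = 0.0508  # m
_D_WICK = 0.007  # m
_L_WICK = 0.0254  # m
_EMIS_GLOBE = 0.95
_ALB_GLOBE = 0.05
_EMIS_WICK = 0.95
_ALB_WICK = 0.4
_EMIS_SFC = 0.999
_ALB_SFC = 0.45
_CP_AIR = 1003.5  # J kg-1 K-1
_M_AIR = 28.97
_M_H2O = 18.015
_R_GAS = 8314.34
_R_AIR = _R_GAS / _M_AIR
_PR = _CP_AIR / (_CP_AIR + 1.25 * _R_AIR)  # Prandtl number of air, ~0.737
_RATIO = _CP_AIR * _M_AIR / _M_H2O
_P_REF_HPA = 1013.25

_TOL = 0.02  # degC convergence
_MAX_ITER = 100
_MIN_SPEED = 0.13  # m/s floor: free-convection stirring never vanishes


class GlobeConvergenceError(RuntimeError):
    """Raised when a globe/wick energy balance fails to converge."""


@dataclass(frozen=True)
class GlobeSet:
    """Globe-instrument temperatures for one time-point (degC)."""

    t_g: float
    t_nwb: float
    wbgt: float
    wbgt_clouds: float
    t_mr: float


# --- air properties --------------------------------------------------------

def _esat_hpa(tk: float) -> float:
    """Saturation vapour pressure over water (hPa), Buck with 1.004 enhancement."""
    return 1.004 * 6.1121 * math.exp(17.502 * (tk - 273.15) / (tk - 32.18))


def _dew_point_k(e_hpa: float) -> float:
    y = math.log(e_hpa / (1.004 * 6.1121))
    return (273.15 * 17.502 - 32.18 * y) / (17.502 - y)


def _viscosity(tk: float) -> float:
    """Dynamic viscosity of air (kg m-1 s-1), Sutherland."""
    return 1.458e-6 * tk**1.5 / (tk + 110.4)


def _thermal_conductivity(tk: float) -> float:
    return (_CP_AIR + 1.25 * _R_AIR) * _viscosity(tk)


def _diffusivity(tk: float, p_hpa: float) -> float:
    """Diffusivity of water vapour in air (m2/s)."""
    return 2.26e-5 * (tk / 273.15) ** 1.81 * (_P_REF_HPA / p_hpa)


def _latent_heat(tk: float) -> float:
    """Latent heat of vaporisation (J/kg)."""
    return 2.501e6 - 2370.0 * (tk - 273.15)


def _emis_atm(tk: float, rh_frac: float) -> float:
    """Sky emissivity from vapour pressure (Brunt-type)."""
    e = rh_frac * _esat_hpa(tk)
    return 0.575 * e**0.143


def _h_sphere(diam: float, tk: float, p_hpa: float, speed: float) -> float:
    """Convective coefficient for a sphere (W m-2 K-1), Nu = 2 + 0.6 Re^0.5 Pr^(1/3)."""
    density = p_hpa * 100.0 / (_R_AIR * tk)
    re = max(speed, _MIN_SPEED) * density * diam / _viscosity(tk)
    nu = 2.0 + 0.6 * math.sqrt(re) * _PR ** (1.0 / 3.0)
    return nu * _thermal_conductivity(tk) / diam


def _h_cylinder(diam: float, tk: float, p_hpa: float, speed: float) -> float:
    """Convective coefficient for a cylinder in cross flow (W m-2 K-1)."""
    density = p_hpa * 100.0 / (_R_AIR * tk)
    re = max(speed, _MIN_SPEED) * density * diam / _viscosity(tk)
    nu = 0.281 * re**0.6 * _PR**0.44
    return nu * _thermal_conductivity(tk) / diam


def direct_beam_fraction(q_solar: float, cza: float, d_solar: float = 1.0) -> float:
    """Direct fraction of total solar radiation from the clearness ratio.

    Parameterised from s = measured/TOA irradiance; clipped to [0, 0.9] and
    zero for a sun effectively on the horizon.
    """
    if q_solar <= 0.0 or cza <= math.cos(math.radians(89.5)):
        return 0.0
    toa = 1367.0 * cza / d_solar**2
    s = min(q_solar / toa, 0.85)
    if s <= 0.0:
        return 0.0
    fdir = math.exp(3.0 - 1.34 * s - 1.65 / s)
    return min(max(fdir, 0.0), 0.9)


# --- solvers ---------------------------------------------------------------

def globe_temperature(
    t_air: float,
    v2: float,
    q_solar: float,
    p_air: float,
    cza: float = 1.0,
    fdir: float | None = None,
    rh: float = 50.0,
) -> float:
    """Black-globe temperature (degC) from the 5 cm globe energy balance.

    ``p_air`` in kPa.  ``cza`` is the cosine of the solar zenith angle used
    to split the direct beam over the globe cross-section; ``fdir`` overrides
    the direct-beam fraction (otherwise parameterised from the clearness
    ratio).  ``rh`` only enters through the sky emissivity.
    """
    if v2 < 0.0:
        raise ValueError("wind speed must be non-negative")
    p_hpa = p_air * 10.0
    tk_air = t_air + 273.15
    if fdir is None:
        fdir = direct_beam_fraction(q_solar, cza)
    if q_solar <= 0.0:
        q_solar, fdir = 0.0, 0.0
    cza_eff = max(cza, math.cos(math.radians(89.5)))
    e_atm = _emis_atm(tk_air, rh / 100.0)

    tg = tk_air
    for _ in range(_MAX_ITER):
        t_ref = 0.5 * (tg + tk_air)
        h = _h_sphere(_D_GLOBE, t_ref, p_hpa, v2)
        tg_new = (
            0.5 * (e_atm * tk_air**4 + _EMIS_SFC * tk_air**4)
            - h / (_EMIS_GLOBE * _SIGMA) * (tg - tk_air)
            + q_solar
            / (2.0 * _EMIS_GLOBE * _SIGMA)
            * (1.0 - _ALB_GLOBE)
            * (fdir * (1.0 / (2.0 * cza_eff) - 1.0) + 1.0 + _ALB_SFC)
        ) ** 0.25
        if abs(tg_new - tg) < _TOL:
            return tg_new - 273.15
        tg = 0.9 * tg + 0.1 * tg_new
    raise GlobeConvergenceError(
        f"globe balance did not converge (t_air={t_air}, v2={v2}, q_solar={q_solar})"
    )


def natural_wet_bulb(
    t_air: float,
    rh: float,
    v2: float,
    q_solar: float,
    p_air: float,
    cza: float = 1.0,
    fdir: float | None = None,
) -> float:
    """Natural wet-bulb temperature (degC) from the wick energy balance.

    Radiative and solar load on the wetted cylinder balance convective and
    evaporative exchange; the heat/mass-transfer analogy carries the
    (Pr/Sc)^0.56 correction.
    """
    if not 0.0 <= rh <= 100.0:
        raise ValueError("relative humidity must be within 0..100%")
    p_hpa = p_air * 10.0
    tk_air = t_air + 273.15
    if fdir is None:
        fdir = direct_beam_fraction(q_solar, cza)
    if q_solar <= 0.0:
        q_solar, fdir = 0.0, 0.0
    e_air = (rh / 100.0) * _esat_hpa(tk_air)
    e_atm = _emis_atm(tk_air, rh / 100.0)
    sza = math.acos(max(-1.0, min(1.0, cza)))

    twb = _dew_point_k(e_air) if e_air > 0.0 else tk_air - 10.0
    for _ in range(_MAX_ITER):
        t_ref = 0.5 * (twb + tk_air)
        h = _h_cylinder(_D_WICK, t_ref, p_hpa, v2)
        f_atm = _SIGMA * _EMIS_WICK * (
            0.5 * (e_atm * tk_air**4 + _EMIS_SFC * tk_air**4) - twb**4
        ) + (1.0 - _ALB_WICK) * q_solar * (
            (1.0 - fdir) * (1.0 + 0.25 * _D_WICK / _L_WICK)
            + fdir * (math.tan(sza) / math.pi + 0.25 * _D_WICK / _L_WICK)
            + _ALB_SFC
        )
        density = p_hpa * 100.0 / (_R_AIR * t_ref)
        sc = _viscosity(t_ref) / (density * _diffusivity(t_ref, p_hpa))
        e_wick = _esat_hpa(twb)
        twb_new = (
            tk_air
            - _latent_heat(t_ref) / _RATIO * (e_wick - e_air) / (p_hpa - e_wick)
            * (_PR / sc) ** 0.56
            + f_atm / h
        )
        if abs(twb_new - twb) < _TOL:
            return twb_new - 273.15
        twb = 0.9 * twb + 0.1 * twb_new
    raise GlobeConvergenceError(
        f"wet-bulb balance did not converge (t_air={t_air}, rh={rh}, v2={v2})"
    )


def wbgt(t_nwb: float, t_g: float, t_air: float) -> float:
    """ISO 7243 wet bulb globe temperature: 0.7 Tnwb + 0.2 Tg + 0.1 Tair."""
    return 0.7 * t_nwb + 0.2 * t_g + 0.1 * t_air


def mean_radiant_temperature(t_g: float, t_air: float, v2: float) -> float:
    """Mean radiant temperature (degC) inverted from the globe reading.

    ``t_mr = 100 [ ((t_g+273)/100)^4 + h_c (t_g - t_air) ]^(1/4) - 273`` with
    ``h_c = max(0.4 |t_g - t_air|^0.25, 2.5 v2^0.6)`` (natural vs forced
    convection, on the (K/100)^4 radiative scale).  Equals ``t_air`` when the
    globe shows no radiant asymmetry.
    """
    hc = max(0.4 * abs(t_g - t_air) ** 0.25, 2.5 * v2**0.6)
    bracket = ((t_g + 273.0) / 100.0) ** 4 + hc * (t_g - t_air)
    if bracket < 0.0:
        bracket = 0.0
    return 100.0 * bracket**0.25 - 273.0


def globe_set(
    t_air: float,
    rh: float,
    v2: float,
    p_air: float,
    q_solar: float,
    cza: float = 1.0,
    transmittance: float = 1.0,
) -> GlobeSet:
    """Solve the full instrument set for one time-point.

    ``t_g``, ``t_nwb``, ``wbgt`` and ``t_mr`` use the unattenuated solar
    load; ``wbgt_clouds`` re-solves both instruments with the cloud
    transmittance applied to ``q_solar``.
    """
    t_g = globe_temperature(t_air, v2, q_solar, p_air, cza=cza, rh=rh)
    t_nwb = natural_wet_bulb(t_air, rh, v2, q_solar, p_air, cza=cza)
    if transmittance >= 1.0 or q_solar <= 0.0:
        t_g_c, t_nwb_c = t_g, t_nwb
    else:
        q_c = q_solar * transmittance
        t_g_c = globe_temperature(t_air, v2, q_c, p_air, cza=cza, rh=rh)
        t_nwb_c = natural_wet_bulb(t_air, rh, v2, q_c, p_air, cza=cza)
    return GlobeSet(
        t_g=t_g,
        t_nwb=t_nwb,
        wbgt=wbgt(t_nwb, t_g, t_air),
        wbgt_clouds=wbgt(t_nwb_c, t_g_c, t_air),
        t_mr=mean_radiant_temperature(t_g, t_air, v2),
    )
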