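"""Personal factors: body, activity and clothing catalogues.

Resting metabolism is Harris-Benedict (kcal/day, converted to W with the
thermochemical calorie), body surface area is Du Bois, and the activity and
clothing catalogues carry the ISO 8996 heat-production levels and ISO 9920
style ensemble properties used throughout the assessment models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from pydantic import BaseModel, Field

__all__ = [
    "CLO_SI",
    "I_A_STATIC",
    "PersonProfile",
    "ActivityProfile",
    "ClothingEnsemble",
    "ACTIVITY_LEVELS",
    "CLOTHING_CATALOGUE",
    "clo_to_si",
    "si_to_clo",
    "resting_metabolic_rate",
    "body_surface_area",
    "metabolic_heat",
    "activity_profile",
    "clothing_catalogue",
]

CLO_SI = 0.155  # m2 K/W per Clo
I_A_STATIC = 0.085  # m2 K/W, air-layer insulation of a nude manikin

_KCAL_DAY_TO_W = 4184.0 / 86400.0  # thermochemical calorie over one day


class PersonProfile(BaseModel):
    """Body characteristics, acclimatisation state and advice profile."""

    age: float = Field(gt=0.0)
    height: float = Field(ge=100.0, le=230.0)  # cm
    weight: float = Field(ge=30.0, le=200.0)  # kg
    sex: Literal["male", "female"]
    acclimatised: bool = False
    position: Literal["standing"] = "standing"
    profile: Literal["personal", "senior-caregiver", "child-caregiver"] = "personal"


@dataclass(frozen=True)
class ActivityProfile:
    """Activity level with associated metabolic heat production.

    ``external_work`` is fixed at zero and ``v_walk`` is 0.8 m/s for every
    non-rest level (slow body movement approximating the air-pumping effect
    in clothing) and 0 at rest.
    """

    level: str
    q_met_w: float
    q_met_wm2: float
    external_work: float = 0.0
    v_walk: float = 0.8


class ClothingEnsemble(BaseModel):
    """Ensemble insulation, vapour permeability and air permeability."""

    name: str
    icl: float = Field(ge=0.0)  # basic insulation, m2 K/W
    im_st: float = Field(gt=0.0, le=1.0)  # static vapour-permeability index
    p_air_perm: float = Field(gt=0.0)  # air permeability, L m-2 s-1

    @property
    def icl_clo(self) -> float:
        return si_to_clo(self.icl)


# ISO 8996 style whole-body heat production per activity level (W)
ACTIVITY_LEVELS: dict[str, float | None] = {
    "rest": None,  # Harris-Benedict resting metabolic rate
    "low": 180.0,
    "moderate": 300.0,
    "high": 415.0,
    "very-high": 520.0,
}

# name -> (icl m2K/W, im_st, p_air L m-2 s-1)
CLOTHING_CATALOGUE: dict[str, tuple[float, float, float]] = {
    "summer": (0.078, 0.45, 200.0),
    "casual": (0.124, 0.38, 100.0),
    "business": (0.155, 0.38, 50.0),
    "double-layer": (0.233, 0.38, 10.0),
    "winter": (0.310, 0.38, 5.0),
    "extreme-winter": (0.388, 0.38, 5.0),
}


def clo_to_si(clo: float) -> float:
    """Convert clothing insulation from Clo to m2 K/W (1 Clo = 0.155)."""
    return clo * CLO_SI


def si_to_clo(icl: float) -> float:
    return icl / CLO_SI


def resting_metabolic_rate(profile: PersonProfile) -> float:
    """Harris-Benedict resting metabolic rate in W.

    Sex-specific kcal/day regression on height (cm), weight (kg) and age
    (years), converted with 4184 J/kcal over 86400 s.
    """
    h, w, a = profile.height, profile.weight, profile.age
    if profile.sex == "male":
        kcal_day = 66.4730 + 5.0033 * h + 13.7516 * w - 6.7550 * a
    else:
        kcal_day = 655.0955 + 1.8496 * h + 9.5634 * w - 4.6756 * a
    return kcal_day * _KCAL_DAY_TO_W


def body_surface_area(height: float, weight: float) -> float:
    """Du Bois body surface area (m2) from height (cm) and weight (kg)."""
    if height <= 0.0 or weight <= 0.0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def metabolic_heat(level: str, profile: PersonProfile) -> tuple[float, float]:
    """Metabolic heat production (W, W/m2) for an activity level.

    Catalogue wattage for the named level; resting metabolism from
    Harris-Benedict.  The areal rate divides by Du Bois surface area.
    """
    if level not in ACTIVITY_LEVELS:
        raise ValueError(
            f"unknown activity level {level!r}; expected one of {sorted(ACTIVITY_LEVELS)}"
        )
    watts = ACTIVITY_LEVELS[level]
    if watts is None:
        watts = resting_metabolic_rate(profile)
    return watts, watts / body_surface_area(profile.height, profile.weight)


def activity_profile(level: str, profile: PersonProfile) -> ActivityProfile:
    w, wm2 = metabolic_heat(level, profile)
    return ActivityProfile(
        level=level,
        q_met_w=w,
        q_met_wm2=wm2,
        v_walk=0.0 if level == "rest" else 0.8,
    )


def clothing_catalogue(
    name: str,
    icl: float | None = None,
    im_st: float | None = None,
    p_air_perm: float | None = None,
) -> ClothingEnsemble:
    """Look up a catalogue ensemble, optionally fine-tuning its properties.

    Unknown names are accepted only when all three properties are supplied
    (a fully custom ensemble).
    """
    if name in CLOTHING_CATALOGUE:
        base_icl, base_im, base_p = CLOTHING_CATALOGUE[name]
        return ClothingEnsemble(
            name=name,
            icl=base_icl if icl is None else icl,
            im_st=base_im if im_st is None else im_st,
            p_air_perm=base_p if p_air_perm is None else p_air_perm,
        )
    if icl is None or im_st is None or p_air_perm is None:
        raise ValueError(
            f"unknown clothing ensemble {name!r}; expected one of "
            f"{sorted(CLOTHING_CATALOGUE)} or custom icl/im_st/p_air_perm values"
        )
    return ClothingEnsemble(name=name, icl=icl, im_st=im_st, p_air_perm=p_air_perm)
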