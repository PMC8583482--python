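# Methods

This note documents the models implemented in `climstress`, the defaults
and why they were chosen, the numerical machinery, what the synthetic
weather generator does and does not emulate, and known limitations.

## Derived environmental variables

Standard forecasts carry air temperature, relative humidity, pressure,
10 m wind and cloud cover; the thermal models need more.

* **Water vapour pressure** uses the Antoine relation
  `P_v = 0.1 (RH/100) exp(18.965 − 4030/(T+235))` kPa.  The same relation,
  inverted at a suggested indoor temperature, yields the advisory indoor
  humidity (outdoor vapour pressure over indoor saturation, capped at
  100 %).
* **2 m wind** scales the 10 m forecast wind by `(2/10)^0.25 ≈ 0.669`
  (neutral-stability power profile).  The exact power form is used rather
  than a rounded 0.67 so no rounding error propagates into the globe
  solvers.
* **Solar radiation.** Solar elevation comes from the low-precision
  astronomical-almanac algorithm (mean solar longitude and anomaly,
  ecliptic longitude, declination, Greenwich sidereal time; hour angle from
  UTC + longitude, so no timezone database is needed).  The test suite
  cross-checks it against an independently coded NOAA/Meeus-style
  calculator; agreement is well inside 2° over a year × site grid, far
  better than the globe model needs.  Top-of-atmosphere irradiance is
  `1367 max(0, cosθ_z/d²)` W/m² with `d` from the standard two-harmonic
  distance series; the clear-sky surface value applies a maximum
  atmospheric transmission of 0.85.  Cloud cover in octa attenuates by the
  transmittance ratio `1 − 0.75 (N/8)^3.4` (0.25 at full overcast).
* **Worst-case radiation policy** (engine level, not here): heat
  assessments use the *unattenuated* clear-sky load — advice should hold
  for the moments a person stands in full sun; cold assessments force
  8-octa overcast.  Both bias the index toward caution.

Cloud cover is stored internally in octa; percent inputs are rounded to
the nearest octa at the file boundary.  Timestamps are UTC throughout.

## Globe instruments (WBGT)

Black-globe and natural wet-bulb temperatures are solved from the
Liljegren steady-state energy balances for a 5 cm globe and a standard
wetted wick: long-wave exchange with a Brunt-type sky emissivity
(`0.575 e^{1/7}`, e in hPa) and the ground, solar gain with the direct
fraction parameterised from the surface/TOA clearness ratio
(`f_dir = exp(3 − 1.34 s − 1.65/s)`, clipped to [0, 0.9]), convection from
sphere (`Nu = 2 + 0.6 Re^{1/2} Pr^{1/3}`) and cylinder
(`Nu = 0.281 Re^{0.6} Pr^{0.44}`) correlations, and — for the wick — an
evaporative term through the heat/mass-transfer analogy with a
`(Pr/Sc)^{0.56}` correction.  A damped fixed-point iteration (damping 0.9,
tolerance 0.02 °C, max 100 iterations, initial guess at air temperature /
dew point) mirrors reference-implementation practice; non-convergence
raises with diagnostics rather than returning garbage.  A 0.13 m/s wind
floor keeps the Reynolds number physical in still air.

WBGT is the ISO 7243 outdoor weighting `0.7 T_nwb + 0.2 T_g + 0.1 T_air`.
Mean radiant temperature inverts the globe reading,
`T_mr = 100 [((T_g+273)/100)^4 + h_c (T_g − T_air)]^{1/4} − 273` with
`h_c = max(0.4 |ΔT|^{0.25}, 2.5 v₂^{0.6})` on the (K/100)⁴ scale — the
standard globe-thermometer inversion with natural- and forced-convection
branches; it reduces exactly to `T_mr = T_air` when the globe shows no
radiant asymmetry.  A negative bracket (physically impossible radiant
field) is clamped to zero.

Note one physical consequence: with zero solar load under a clear, dry sky
the globe equilibrates ~1 °C *below* air temperature, because the sky's
effective emissivity is below one.  This is the Liljegren balance working
as intended, not solver error.

## Personal factors

* Resting metabolism: Harris–Benedict by sex (kcal/day from height in cm,
  weight in kg, age in years), converted with the thermochemical calorie
  (4184 J) over 86 400 s; ~87 W for a 40-year-old 180 cm/80 kg male.
* Body surface area: Du Bois `0.007184 w^{0.425} h^{0.725}` m².
* Activity catalogue (whole-body heat production): low 180 W, moderate
  300 W, high 415 W, very-high 520 W; rest uses Harris–Benedict.  Areal
  rates divide by Du Bois area.  External work is fixed at zero and the
  walking speed fed to the dynamic-clothing corrections is 0.8 m/s for all
  non-rest levels (a proxy for air pumping in clothing), 0 at rest.
* Clothing catalogue (insulation m²K/W, static vapour-permeability index,
  air permeability L/m²s): summer (0.078, 0.45, 200), casual (0.124, 0.38,
  100), business (0.155, 0.38, 50), double-layer (0.233, 0.38, 10), winter
  (0.310, 0.38, 5), extreme-winter (0.388, 0.38, 5).  1 Clo = 0.155 m²K/W.
  Users may fine-tune any of the three properties.

## Heat branch

The clothing adjustment value is parameterised on static evaporative
resistance: `f_cl = 1 + 1.81 I_cl` below 2 Clo (power form
`1.2424 I_cl[Clo]^{0.1546}` above — the branch threshold is placed at
2 Clo, reading the published branch condition in Clo, the only reading
under which both branches are near-continuous),
`R_{e,T,s} = 0.16 (I_a/f_cl + I_cl)` with the nude air layer
`I_a = 0.085` m²K/W divided by the area factor (the ISO 9920
total-insulation convention), and `CAV = 5.81 ln R_{e,T,s} + 20.7` °C.
The reference cotton ensemble lands near zero; a business suit adds
+1.3 °C, summer attire subtracts ~0.9 °C.

Reference limits and the HRL→index mapping are given in the README.  The
index is clamped at +4; HRL is kept as a ratio internally (percent is
presentation).  Category bands are not-significant/low/moderate/high at
0.8/1.0/1.2.

## Predicted Heat Strain (ISO 7933)

A 1-minute time-stepping heat-balance simulation up to 480 min: required
core temperature follows metabolic rate (`0.0036 M + 36.6`, τ = 10 min);
skin temperature relaxes (τ = 3 min) to clothed/nude equilibrium
regressions interpolated between 0.2 and 0.6 Clo; wind and body movement
reduce clothing insulation and evaporative resistance through the standard
correction factors; respiratory convective and evaporative losses use the
expired-air regressions; the clothing surface temperature is solved each
minute with a linearised radiative coefficient (standing radiating-area
fraction 0.77).  The predicted sweat rate tracks the required rate with a
10 min time constant under acclimatisation-dependent maxima (wettedness
0.85 vs 1.0; maximum sweat rate +25 % when acclimatised).  Outputs used
downstream: `dle_hot`, the first minute rectal temperature reaches 38 °C
(480 = no limit within a shift), and accumulated sweat in grams, reported
both as a total and per hour since the in-app figure is an hourly rate.
Inputs outside the model's validity envelope (15–50 °C etc.) attach
warnings instead of failing; the engine decides what to do.

## Cold branch (ISO 11079 + windchill)

IREQ solves `M − W = E_res + C_res + E + R + C` for the clothing
insulation that closes the balance at two criteria: *neutral*
(`T_sk = 35.7 − 0.0285 M`, wettedness `0.001 M`) and *minimal*
(`T_sk = 33.34 − 0.0354 M`, wettedness 0.06, no thermoregulatory
sweating).  Dry exchange passes through the clothing area factor
`1 + 1.197 I_clr` with `h_c = 3.5 + 5.2 v` (v < 1 m/s) or `8.7 v^{0.6}`;
the evaporative path uses a Lewis-type relation with a fixed ensemble
permeability index of 0.38.  The damped fixed-point solve of the required
resultant insulation is cross-checked in the tests against nested brentq
root-finds of the same balance.  The required *resultant* insulation is
converted to the basic insulation a user can compare with a catalogue
value by dividing out the wind/body-motion reduction factor
`exp([−0.0512(v−0.4) + 0.000794(v−0.4)² − 0.0639 w] · p^{0.144})`, which
scales with the ensemble's air permeability `p` — so a wind-tight shell
measurably lowers the requirement in wind, as it should.

When the worn insulation is below the minimal requirement, the duration
limited exposure is the permissible body heat debt (40 Wh/m²) over the net
cooling rate at the worn (resultant) insulation.

Windchill is `13.12 + 0.6215 T + (0.3965 T − 11.37) v₁₀^{0.16}` with the
10 m wind **in m/s** — the 0.16 exponent doubles as the 10 m→2 m scaling,
so the wind is deliberately not pre-scaled.  Below the 1.34 m/s validity
floor the air temperature is returned.  A consequence of the m/s
convention is that near the floor, at mildly cold temperatures, the
regression can sit slightly above air temperature; from ~4.5 m/s it always
cools.  The frostbite flag is raised whenever windchill is below 0 °C.

The cold index mapping (README) is continuous at both breakpoints; the
degenerate case `I_min = I_neu` returns 0 for any adequately dressed user
and the underdressed branch otherwise.  The index is clamped at −4.

## Indoor branch (ISO 7730)

Fanger PMV with the indoor conventions: radiant temperature equals air
temperature, air speed 0.2 m/s (windows closed) or 0.5 m/s (open).  The
clothing surface temperature iteration converges to 1e−5 °C with the
natural/forced convective branch re-selected each step.
`PPD = 100 − 95 exp(−0.03353 PMV⁴ − 0.2179 PMV²)` (minimum 5 %).  The
indoor index *equals* the PMV.

The suggested indoor temperature is a configurable adaptive-comfort linear
relation (`0.33 T_out + 18.8` °C, ±1 °C per thermostat notch from the
neutral setting 3, clamped to 16–30 °C) — deliberately marked advisory: the
assessment always uses user-entered values.  The thermostat semantics
beyond "3 is neutral" and the original adaptive algorithm are not fully
specified anywhere public, so this default is a documented stand-in.

## Engine policies

* Mode dispatch: indoor flag → PMV; otherwise compute the heat screening
  and switch to it when HRL ≥ 0.8 (the first WBGT alert band — the cold
  model is deliberately stretched upward until the WBGT thresholds take
  over, since no single ISO model bridges the gap); otherwise the cold
  branch.  Dispatch is total: every outdoor sample gets exactly one of
  heat/cold.
* Notifications are emitted as codes with numeric parameters; message text
  is presentation keyed by code + profile + language.  Caregiver profiles
  (senior/child) swap advice audience, never the index.  Heat gates:
  alert-approach inside 0.8 < HRL < 1.0; clothing tip iff CAV > 0;
  rescheduling iff activity above moderate; hydration always in heat mode;
  fans up to moderate activity and cooling vests from high activity
  (both configurable — the published decision tree gates them "on
  activity" without thresholds).  Cold gates: wind-stopper iff windchill ≤
  air − 2 °C; frostbite iff windchill < 0 °C; underdressed → exposure
  minutes; overdressed → sweat prevention.
* Self-reported perception is echoed as a sensitivity note only; it never
  moves the index.
* Forecasts: one assessment per 3 h sample; contiguous windows with
  |index| > 2 are flagged with start/end/peak.
* The sensitivity grid fixes the vapour pressure to that of 20 °C/50 % RH
  (RH capped at 100 % at low temperatures), wind 1 m/s, no sun, and a
  1.80 m/80 kg reference person, then sweeps air temperature × activity.

## Synthetic weather generator

Four scenarios (heatwave, arctic, temperate, diurnal-cycle) each fix a
site, season and diurnal envelopes; seeded jitter is clipped back inside
the stated temperature spans (heatwave 28–38 °C, arctic −25…−5 °C).  The
temperature phase peaks ~2 h after local solar noon so radiation and
temperature are mutually consistent.  Nine samples at 3 h spacing cover
24 h.  The generator emulates the *statistical envelope* of a forecast,
not weather dynamics: no fronts, no precipitation events, no
pressure/wind coupling, and cloud cover independent of humidity.  Passing
tests therefore demonstrate correct model behaviour across realistic
input ranges, not skill on any real forecast feed.

## Numerical choices

Fixed-point solvers are damped (0.9 old/0.1 new for the globe
instruments; 0.7/0.3 for IREQ) with explicit iteration caps and
convergence tolerances (0.02 °C globes, 1e−5 m²K/W IREQ, 1e−5 °C PMV
surface temperature).  Degenerate inputs are handled by continuous
extension (cold mapping with a zero-width band), clamping (negative
radiant bracket, index range), or validity warnings (PHS/PMV envelopes,
IREQ metabolic clipping into 58–290 W/m²) rather than exceptions, except
where a precondition is genuinely violated (negative wind, RH out of
range), which raises.

## Cross-checking strategy

No independent thermal-comfort reference implementation is bundled, so
every solver is verified by a structurally different computational route
written in the test suite: a Meeus-style solar calculator against the
almanac algorithm; scipy.brentq root-finds of explicitly written balance
residuals against the damped fixed-point globe, IREQ and PMV solves; and
a closed-form steady-state heat-balance computation against the PHS
simulation's asymptotic sweat rate.  These catch solver and bookkeeping
errors; they share the models' published coefficient sets with the
implementation, so transcription errors in a coefficient would need the
property/limit tests (monotonicities, physical limits, worked values) to
surface.

## Limitations

Altitude/pressure effects on heat balance are not modelled (the inputs
carry pressure, the cold model ignores it).  Local extremity cooling is
covered only through windchill advice, not modelled insulation of hands
and face.  Thermal history is ignored — every assessment starts from
neutral.  The risk thresholds are adult-worker values; caregiver profiles
change wording only.  The PHS model is nominally valid 15–50 °C and IREQ
−50…+10 °C (stretched upward by the handover policy); between roughly 10
and 15 °C in cool-but-not-cold weather the cold branch is operating above
its nominal domain, which is flagged in the result warnings.
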