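# climstress

Personal heat- and cold-stress assessment from ordinary weather forecasts.

`climstress` answers the question a weather report cannot: *how thermally
stressful is this weather for **this** person, doing **this** work, in
**these** clothes?*  It implements the ISO-based model chain used by
occupational-health thermal warning tools — outdoor heat screening with the
wet bulb globe temperature (WBGT, ISO 7243) computed by the Liljegren
instrument models, Predicted Heat Strain (PHS, ISO 7933) for exposure
limits and sweat loss, required clothing insulation (IREQ, ISO 11079) with
the windchill index for cold, and Fanger PMV/PPD (ISO 7730) indoors — and
collapses the result into a single **thermal stress index** from −4
(extreme cold) to +4 (extreme heat), where |index| ≤ 1 means low stress.

It is a library plus a small CLI, intended for occupational-health
researchers, tool builders and anyone who wants reproducible, personalised
thermal risk numbers offline: a deterministic synthetic-forecast generator
stands in for any live weather service.

## The index in brief

Outdoors, the heat branch follows the WBGT screening chain:

    WBGT        = 0.7 T_nwb + 0.2 T_g + 0.1 T_air          (Liljegren T_nwb, T_g)
    WBGT_eff    = WBGT + CAV(I_cl)                          (clothing adjustment)
    WBGT_ref    = 56.7 − 11.5 log10 M   (acclimatised)      (alert limit, M in W)
                  59.9 − 14.1 log10 M   (unacclimatised)
    HRL         = WBGT_eff / WBGT_ref                       (heat risk level)

HRL maps piecewise-linearly onto the index (HRL 0.8 → 1, 1.0 → 2, 1.2 → 3).
If HRL stays below the 0.8 alert band the engine switches to the cold
branch, which compares the worn insulation against the IREQ requirements:

    index = −1 − (I_min − I_user)                   underdressed
    index = −1 + (I_user − I_min)/(I_neu − I_min)   between minimal and neutral
    index = I_user − I_neu                          overdressed (in Clo)

Indoors the index equals the PMV.  Heat assessments ignore cloud
attenuation of the sun and cold assessments assume full overcast — both
deliberate worst-case policies.

## Worked example

Generate a synthetic Mediterranean heat episode, describe the person in a
TOML file, and assess midday:

```toml
# ctx.toml
[person]
age = 42
height = 178
weight = 78
sex = "male"
acclimatised = false

[activity]
level = "moderate"     # 300 W sustained work

[clothing]
name = "summer"        # 0.5 Clo, highly permeable
```

```sh
climstress synth --scenario heatwave --seed 1 --out weather.json
climstress assess --weather weather.json --config ctx.toml \
    --at 2021-07-15T12:00:00+00:00
```

prints (abridged):

```json
{
 "mode": "heat",
 "index": 3.04,
 "heat": {
  "wbgt_effective": 30.95,
  "cav": -0.87,
  "wbgt_ref": 24.97,
  "hrl": 1.24,
  "category": "high"
 },
 "phs": {"dle_hot": 18.0, "sweat_per_hour_g": 745.0},
 "notifications": [{"code": "heat.hydrate"}, {"code": "heat.use_fan"},
                   {"code": "heat.exposure_limit", "params": {"minutes": 18.0}}]
}
```

Read: at 37.5 °C under full sun the effective WBGT (31.0 °C — the light
summer ensemble actually *subtracts* 0.9 °C from the measured WBGT) exceeds
this unacclimatised worker's alert limit (25.0 °C) by 24 %, i.e. the high
heat-risk category and index 3.0; the PHS simulation predicts the rectal
temperature reaches 38 °C after 18 minutes of continuous worst-case
exposure, sweating ~0.75 L/h.

`climstress forecast` produces the 24 h index series with flagged windows
where |index| > 2, and `climstress sweep --plot grid.png` renders the
air-temperature × activity sensitivity heatmap.

## Forecast JSON dialect

`read_forecast`/`write_forecast` use one JSON document per forecast:
`city.coord.{lat,lon}` plus a `list` of 3-hourly steps, each with `dt`
(unix UTC), `main.temp` (°C), `main.humidity` (%), `main.pressure` (hPa),
`wind.speed` (m/s; km/h if `wind.unit` says so), `clouds.all` (% cover,
converted to octa at the boundary) and optional `rain.3h`/`snow.3h`.  This
mirrors the common 5-day/3-hour forecast-provider schema so real provider
payloads need only minimal massaging.

See `docs/methods.md` for the full model description, parameter defaults,
numerical choices and limitations.
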