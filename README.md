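# aeroalert

Dynamic aeroconservation analysis for nocturnal bird migration.

Twice a year, billions of birds cross the continent at night, and most
of a season's passage at any site happens on a handful of weather-
driven peak nights. Mitigation measures — turning off building lights,
curtailing wind turbines — are costly, so the operational question is
*which nights* to act on to protect a target share of migrants.
`aeroalert` implements and compares three answers for radar-style
migration measurements:

* **idealized dynamic** — with perfect hindsight, the minimum set of
  nights capturing the target fraction of measured passage;
* **forecast dynamic** — a traffic threshold, derived from past years
  on the predicted scale, triggers action nights from a
  gradient-boosted weather forecast of nightly migration;
* **fixed window** — a static calendar window chosen from historical
  data by exhaustive search over widths 1–100 nights.

The measurement chain follows the field's standard quantification:
radar reflectivity η (cm²/km³) times groundspeed (km/h) gives an
activity flux, integrated over each night (trapezoid, 30-min samples),
multiplied by the 0.1-km bin height, summed over 100-m altitude bins
0–3 km and divided by an 11-cm² per-bird cross-section to give nightly
traffic T in birds/km/night. Forecasts model the cube root of the
30-min flux with XGBoost from 13 predictors (latitude, longitude,
height, ordinal date, hour after sunset, and eight atmospheric
covariates) and are evaluated leave-one-year-out. A fully seeded
synthetic-data module generates multi-station, multi-year radar-like
profiles and matched weather with the pulsed structure the analysis
assumes, so the whole pipeline runs without any data download.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

```python
from aeroalert import study

res = study.run_study(seed=1)           # 3 stations x 4 spring seasons
piv = study.nights_by_method(res["results"], target=0.5)
print(piv.mean().round(1))
print("LOYO variance explained:",
      round(res["skill"]["mean_variance_explained"], 3))
```

```
method
fixed_window         19.7
forecast_dynamic     12.3
idealized_dynamic     5.8
dtype: float64
LOYO variance explained: 0.641
```

Reading: to capture 50% of a season's measured passage, hindsight needs
~6 action nights per station-season, the forecast-triggered rule needs
~12, and a historically optimal fixed window needs ~20 — the forecast
halves the cost of the static strategy while hitting a comparable
capture (45.0% vs 44.8% realized on held-out years). The forecast
explains 64% of the variance of the cube-root 30-min migration
intensity on held-out years.

The same pipeline is scriptable from the shell:

```bash
aeroalert simulate --config config.yaml --out data/ --seed 1
aeroalert integrate --profiles data/profiles.csv --out nightly.csv
aeroalert run --config config.yaml --out run/ --seed 1
```

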