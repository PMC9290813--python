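# Methods

`aeroalert` analyses the problem of *when* to trigger aerial-hazard
mitigation (lights-out campaigns, wind-turbine curtailment) for
nocturnally migrating birds. Migratory passage at a site is strongly
pulsed: a small number of nights carry most of a season's birds, and
those nights are largely set by synoptic weather. The package compares
three rules for choosing "action nights" that protect a target fraction
of a season's passage, using radar-style measurements and a
weather-driven forecast.

## Nightly traffic integration

The measurement unit is one 30-min, 100-m-altitude-bin sample of radar
reflectivity η (cm² of scattering cross-section per km³ of air) and
migrant groundspeed (km/h). Their product is an activity flux in
cm²/km²/h. For each height bin the flux is integrated over the night
(trapezoid rule on the 30-min grid, time in hours), multiplied by the
bin thickness (0.1 km), summed over the 30 bins from 0 to 3000 m and
divided by a per-bird radar cross-section of 11 cm², yielding a nightly
traffic rate in birds/km/night:

    T = (1/σ) · Σ_bins Δh · ∫_night η(t,h) · v(t,h) dt ,  σ = 11 cm², Δh = 0.1 km.

Design points:

* **Nights** are labelled by the local calendar date of sunset;
  post-midnight samples keep that label.
* **Interior missing time steps** are bridged by a single trapezoid
  between the flanking samples (the default); a strict mode integrates
  only consecutive 30-min pairs. Nights missing more than 25% of their
  expected steps are flagged incomplete and excluded from season totals;
  nights with fewer than two time steps have *undefined* (not zero)
  traffic.
* **Season validity**: a station-season enters the analysis only with at
  least 100 of its (at most) 102 nights present.
* σ and Δh are parameters with the defaults above, not constants.

## Synthetic data generator

No radar archive ships with the package; a generator reproduces the
statistical structure the analysis depends on, so that every stage is
testable and the full study is reproducible from a seed.

Latent nightly intensity at a station (summed over bins, per night) is

    I_n = A · exp(−(d_n − μ)² / 2s²) · exp(β·F_n + σ_p·z_n),  z_n ~ N(0,1)

* Gaussian phenology envelope: peak ordinal date μ (default
  mid-season), width s = 15 nights, amplitude A = 2·10⁵ cm²/km² (peak
  base traffic ≈ 1.8·10³ birds/km/night, with pulses reaching a few
  10⁴ — the range seen at busy mid-continent sites).
* Weather pulse: F_n is the nightly mean tailwind toward the seasonal
  heading (north in spring, south in autumn), standardized within the
  station-season; β = 0.8.
* Unpredictable pulse noise σ_p = 1.1 (log scale). With these defaults
  the top 10% of nights hold roughly 40–70% of seasonal passage,
  matching the concentration regime of real archives.

Weather lives on a 3-h UTC grid at 100-m heights 0–3000 m. Winds follow
a per-night AR(1) synoptic driver (ρ = 0.7 by default) plus weak
vertical shear and within-night noise; temperature ramps seasonally and
lapses with height; pressure, humidity, cloud and visibility are
correlated, bounded fields. The grid covers every season date plus one
trailing day because nights labelled by sunset run past midnight UTC.

Within a night, intensity follows a Beta(2,3)-shaped curve (zero at
sunset and sunrise, peak at one-third of the night) sampled every
30 min; across height it decays exponentially with scale 1000 m.
Groundspeed is a constant 12 m/s airspeed plus the tailwind component,
floored at 1 km/h. Observed η is the latent flux divided by groundspeed
times log-normal noise (σ_obs = 0.3). Nights drop out independently
with probability `dropout_rate` (default 0: with a 102-night season the
≥100-night filter tolerates at most two missing nights, so a
non-trivial default would invalidate most simulated seasons; dropout is
exercised explicitly in tests). Truth records keep every night's latent
total, including dropped nights.

A separate *forecast-weather* channel equals the reanalysis weather
plus Gaussian error on the wind components and temperature with SD
`forecast_error_sd` times each field's marginal SD; 0 reproduces the
idealized limit. This stands in for the difference between a true
forecast product and the reanalysis a model is trained on.

What the generator does **not** emulate: inter-annual phenology shifts
(the envelope peak recurs on the same date every year), spatial
correlation between stations, precipitation contamination, species
mixtures and varying cross-sections, and real solar ephemerides (night
length is fixed per station-season). Passing tests therefore certify
the pipeline's correctness and its behaviour under the stated
statistical regime, not performance on real archives.

## Forecast model

The response is the cube root of η·v per 30-min sample. Thirteen
predictors: latitude, longitude, height above ground; ordinal date and
hour after sunset; zonal and meridional wind, temperature, surface
pressure, relative humidity, total cloud cover, visibility and mean
sea-level pressure, each joined from the weather record at the same
station and height closest in time (ties to the earlier record; samples
with no record within half a grid step are dropped and counted).

Seasonal gradient-boosted tree ensembles (XGBoost) use max_depth 12,
eta 0.01, gamma 1, colsample_bytree 1, min_child_weight 5, subsample
0.7. The round count is not part of that recipe; the library default is
1000 rounds with early stopping (50-round patience) on a 10% random
tuning split. Predictions are cubed, floored at zero and integrated
into nightly traffic with exactly the measured-traffic unit chain.

Evaluation is leave-one-year-out: for each year, a model trained on all
other years (reanalysis channel) predicts that year from the
forecast channel. Skill is variance explained (1 − SSE/SST) on the
cube-root 30-min scale, pooled over stations and heights — the model's
native scale — with the Pearson correlation of nightly totals reported
separately. An assertion verifies that no (station, night) key appears
on both sides of any fold. At least two training years are needed for
transferable skill: a single training year lets depth-12 trees memorise
that year's pulse sequence through ordinal date.

The irreducible limit matters for interpretation: the nightly pulse
z_n is independent of weather, so even a perfect model of the
predictable component tops out near 0.77 variance explained under the
default generator; the trained ensembles reach ≈ 0.65–0.70.

## Action-night selection

For a target capture fraction q (headline 0.5; grid 0.05–0.95 by 0.05):

* **Idealized dynamic** — rank nights by *measured* traffic descending
  (ties to the earlier date) and take the shortest prefix reaching q.
  Ranking by value makes this the minimum-cardinality subset, verified
  in tests against exhaustive enumeration.
* **Forecast dynamic** — from derivation years (all years except the
  year of interest), find the **largest** threshold t such that nights
  with *predicted* traffic ≥ t capture at least q of the *measured*
  passage; apply t unchanged to the evaluation year. Candidates are the
  distinct predicted values. Predictions gate selection and reality
  scores it, so order-preserving miscalibration of the forecast is
  harmless. A literal "smallest threshold" search is degenerate (t → 0
  always qualifies); the largest feasible t is the fewest-nights
  reading, consistent with the minimal-night objective. Derivation-year
  capture is pooled (summed captured traffic over summed totals);
  per-year averaging is available via `pooling="per_year"` and gives
  indistinguishable results under the defaults.
* **Fixed window** — exhaustive search over widths 1–100 and all starts
  (by season-night offset, so a window recurs every year); minimum
  width with mean derivation-year capture ≥ q wins, ties by higher mean
  capture, then earliest start. Missing nights inside the window count
  toward its width (action would still run) but contribute no capture.

Numerical choices: capture comparisons use a 1e-12 slack so exact-target
boundaries are deterministic; zero-total seasons raise errors rather
than returning empty selections; degenerate all-tied predictions fall
back to the smallest candidate threshold with a warning flag.

## Evaluation utilities

Concentration: share of passage in the top ⌈f·N⌉ nights (ceiling
rounding; the convention is stated because "10% of nights" is otherwise
ambiguous). Method comparisons: paired differences in night counts on
matched station-season-year keys, two-sided paired t-tests (flagging
zero-variance degeneracy), and univariate OLS of night counts on
latitude and on longitude with slope, SE and 95% CI. Capture curves
aggregate mean nights and mean realized capture per method and target.

## Reference study and problem sizes

The reference study (`aeroalert.study`) uses three stations
(30°N/−97°E, 38.5°N/−90°E, 43°N/−76°E; night lengths 10.5/10/9.5 h) and
four spring seasons — ≈ 771k 30-min samples. Its LOYO runs use 400
boosting rounds with early stopping and 200k-row seeded training
subsamples so the full study completes in a few minutes on one CPU;
the forecast-error degradation study uses one station and three years.
These sizes are the package's reference configuration; the library
defaults are larger.

## Known limitations

* With only three derivation years, the predicted-scale threshold of
  the forecast-dynamic method transfers noisily to the held-out year:
  in this few-year regime even a perfect forecast of the predictable
  intensity component beats the fixed window on only ≈ 80% of
  station-years, whereas with ~20 derivation years it does so almost
  everywhere. Deep multi-year archives are integral to the method's
  near-universal advantage.
* Variance explained is reported on the pooled 30-min cube-root scale;
  nightly-scale correlation is substantially lower because the nightly
  pulse is unpredictable by construction.
* The generator's log-normal pulse model is a plausible stand-in for
  the empirical night-to-night distribution, not an estimate of it.
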