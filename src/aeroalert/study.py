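"""The package's reference study: a three-station, four-year spring
simulation run end-to-end.

This is the default experimental setup used by the worked example, the
acceptance script and the heavier tests: three stations spanning the
southern/central/northeastern US, four years of 102-night spring
seasons, the default pulsed-migration generator, leave-one-year-out
forecasting and all three selection strategies at the 25/50/75% targets.

Problem sizes (400 boosting rounds with early stopping, 200k-row
training subsamples) are chosen so the full study runs in a few minutes
on one CPU; the library defaults remain larger.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation, forecast, selection, synthetic, traffic
from .config import SimulationConfig, StationConfig
from .pipeline import build_seasons, select_all

DEFAULT_STATIONS = (
    StationConfig("KTX", 30.0, -97.0, 10.5),
    StationConfig("KMO", 38.5, -90.0, 10.0),
    StationConfig("KNY", 43.0, -76.0, 9.5),
)

DEFAULT_YEARS = (2014, 2015, 2016, 2017)

DEFAULT_TARGETS = (0.25, 0.5, 0.75)


def study_config(seed: int, forecast_error_sd: float = 0.0,
                 **overrides) -> SimulationConfig:
    kwargs = dict(
        stations=list(DEFAULT_STATIONS),
        years=list(DEFAULT_YEARS),
        season="spring",
        forecast_error_sd=forecast_error_sd,
        seed=int(seed) % (2**31),
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def run_study(
    seed: int,
    n_rounds: int = 400,
    early_stopping_rounds: int = 30,
    max_train_rows: int | None = 200_000,
    targets=DEFAULT_TARGETS,
    forecast_error_sd: float = 0.0,
) -> dict:
    """Simulate, integrate, forecast (LOYO) and select on the reference
    study; returns all intermediate artifacts."""
    cfg = study_config(seed, forecast_error_sd=forecast_error_sd)
    weather = synthetic.simulate_weather(cfg)
    fweather = synthetic.make_forecast_weather(
        weather, cfg.forecast_error_sd, cfg.seed)
    profiles, truth = synthetic.simulate_migration(cfg, weather)
    nightly = traffic.integrate_profiles(profiles)
    seasons = build_seasons(nightly, cfg, min_nights=100)

    feats = forecast.build_features(profiles, weather)
    ffeats = forecast.build_features(profiles, fweather)
    skill = forecast.loyo_evaluate(
        feats, ffeats, nightly, season=cfg.season, n_rounds=n_rounds,
        early_stopping_rounds=early_stopping_rounds,
        max_train_rows=max_train_rows, seed=cfg.seed,
    )
    results = select_all(seasons, skill["nightly_predictions"], cfg, targets)
    results_df = selection.results_table(results)
    valid = [s for s in seasons.values() if s.valid]
    concentration = evaluation.concentration_table(valid)
    return {
        "config": cfg,
        "profiles": profiles,
        "truth": truth,
        "nightly": nightly,
        "seasons": seasons,
        "skill": skill,
        "results": results_df,
        "concentration": concentration,
    }


def forecast_error_degradation(
    seed: int,
    error_grid=(0.0, 0.5, 1.0),
    n_rounds: int = 150,
    max_train_rows: int | None = 120_000,
) -> pd.DataFrame:
    """LOYO skill as the forecast-weather error grows, shared seeds.

    A single-station, three-year study is simulated once; only the
    forecast-error channel differs between grid points, so differences in
    held-out skill isolate the forecast-degradation effect.
    """
    cfg = SimulationConfig(
        stations=[StationConfig("KER", 36.0, -92.0, 9.0)],
        years=[2013, 2014, 2015],
        seed=int(seed) % (2**31),
    )
    weather = synthetic.simulate_weather(cfg)
    profiles, _ = synthetic.simulate_migration(cfg, weather)
    nightly = traffic.integrate_profiles(profiles)
    feats = forecast.build_features(profiles, weather)
    rows = []
    for err in error_grid:
        fweather = synthetic.make_forecast_weather(weather, err, cfg.seed)
        ffeats = forecast.build_features(profiles, fweather)
        rep = forecast.loyo_evaluate(
            feats, ffeats, nightly, n_rounds=n_rounds,
            early_stopping_rounds=20, max_train_rows=max_train_rows,
            seed=cfg.seed,
        )
        rows.append({"forecast_error_sd": float(err),
                     "mean_variance_explained":
                         rep["mean_variance_explained"]})
    return pd.DataFrame(rows)


def nights_by_method(results: pd.DataFrame, target: float = 0.5):
    """Pivot a results table to per-station-year night counts."""
    at = results[np.isclose(results["target_fraction"], target)]
    return at.pivot_table(index=["station_id", "year"], columns="method",
                          values="n_nights")
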