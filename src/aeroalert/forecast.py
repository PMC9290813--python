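"""Gradient-boosted migration forecasting.

The model predicts 30-min migration intensity on the cube-root scale:
the response is ``(eta x groundspeed)^(1/3)``, with thirteen predictors —
three spatial (latitude, longitude, height above ground), two temporal
(ordinal date, hour after sunset) and eight atmospheric (zonal and
meridional wind, temperature, surface pressure, relative humidity, total
cloud cover, visibility, mean sea-level pressure).  Seasonal ensembles
are trained with XGBoost and evaluated leave-one-year-out: predictions
for the held-out year use the forecast-weather channel, mirroring an
operational forecast issued before each night.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .config import WEATHER_STEP_H
from .errors import TrainingError, ValidationError
from .synthetic import sunset_utc  # noqa: F401  (re-exported convenience)
from . import traffic as _traffic

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "latitude", "longitude", "height_m", "ordinal_date", "hour_after_sunset",
    "uwind_ms", "vwind_ms", "temp_c", "sp_pa", "rh_pct", "tcc_pct",
    "vis_m", "mslp_pa",
]

KEY_COLUMNS = ["station_id", "night_id", "minutes_after_sunset", "height_bin_m"]

DEFAULT_PARAMS = {
    "max_depth": 12,
    "eta": 0.01,
    "gamma": 1,
    "colsample_bytree": 1,
    "min_child_weight": 5,
    "subsample": 0.7,
}


@dataclass
class ForecastModelSpec:
    """Hyperparameters and training scope for one seasonal model."""

    training_years: frozenset
    season: str = "spring"
    n_rounds: int = 1000
    early_stopping_rounds: int = 50
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.training_years = frozenset(int(y) for y in self.training_years)
        if self.n_rounds < 1:
            raise ValidationError("n_rounds must be >= 1")


@dataclass
class TrainedModel:
    booster: xgb.Booster
    spec: ForecastModelSpec
    feature_names: list[str]
    best_iteration: int


def _nearest_weather_time(ts: pd.Series) -> pd.Series:
    """Snap sample timestamps to the nearest 3-h grid time, ties earlier.

    The weather grid is anchored at 00:00 UTC, so rounding is done on
    minutes since the epoch (itself midnight-aligned).
    """
    step = WEATHER_STEP_H * 60
    mins = ts.astype("int64") // (60 * 10**9)
    snapped = (mins + step // 2 - 1) // step * step
    return pd.to_datetime(snapped * 60 * 10**9)


def build_features(
    profiles: pd.DataFrame,
    weather: pd.DataFrame,
    stations=None,
) -> pd.DataFrame:
    """Join each profile sample to its nearest-in-time weather record.

    The join matches station and height exactly (profile bin lower edge to
    weather grid height) and picks the weather timestamp closest to the
    sample time, breaking ties toward the earlier record.  Samples with no
    weather within half the 3-h grid step are dropped with a logged count.
    Returns keys + 13 features + ``response`` + ``year``.
    """
    df = profiles.copy()
    sunset_offset_h = 19.0 - df["longitude"] / 15.0
    sample_utc = (
        pd.to_datetime(df["night_id"])
        + pd.to_timedelta(sunset_offset_h, unit="h")
        + pd.to_timedelta(df["minutes_after_sunset"], unit="m")
    )
    df["weather_time"] = _nearest_weather_time(sample_utc)
    df["hour_after_sunset"] = df["minutes_after_sunset"] / 60.0
    df["ordinal_date"] = pd.to_datetime(df["night_id"]).dt.dayofyear
    df["year"] = pd.to_datetime(df["night_id"]).dt.year

    wx = weather.rename(columns={"timestamp_utc": "weather_time"})
    wx = wx.assign(height_bin_m=wx["height_m"].astype(int))
    merged = df.merge(
        wx.drop(columns=["height_m"]),
        on=["station_id", "weather_time", "height_bin_m"],
        how="left",
    )
    missing = merged["vwind_ms"].isna()
    if missing.any():
        log.warning("dropped %d samples with no weather within ±%d h",
                    int(missing.sum()), WEATHER_STEP_H // 2 + 1)
        merged = merged[~missing]
    merged = merged.copy()
    merged["height_m"] = merged["height_bin_m"].astype(float)
    merged["response"] = np.cbrt(
        merged["eta_cm2_per_km3"] * merged["groundspeed_kmh"]
    )
    cols = KEY_COLUMNS + ["year"] + FEATURE_COLUMNS + ["response"]
    out = merged[cols].sort_values(KEY_COLUMNS, ignore_index=True,
                                   kind="mergesort")
    return out


def train_seasonal_model(
    features: pd.DataFrame, spec: ForecastModelSpec
) -> TrainedModel:
    """Fit one seasonal gradient-boosted ensemble.

    Rows outside ``spec.training_years`` are rejected (leakage guard).  A
    10% random tuning split drives early stopping; training is
    deterministic given ``spec.seed``.
    """
    if len(features) == 0:
        raise TrainingError("empty training set")
    years = set(features["year"].unique().tolist())
    extra = years - set(spec.training_years)
    if extra:
        raise TrainingError(
            f"features contain years {sorted(extra)} outside training_years"
        )
    rng = np.random.default_rng([spec.seed % (2**31), 55001])
    n = len(features)
    tune = rng.random(n) < 0.10
    if tune.all() or (~tune).all():
        tune = np.zeros(n, dtype=bool)  # tiny inputs: no tuning split
    X = features[FEATURE_COLUMNS].to_numpy(dtype=np.float32)
    y = features["response"].to_numpy(dtype=np.float32)
    params = dict(spec.params)
    params.setdefault("tree_method", "hist")
    params["seed"] = spec.seed % (2**31)
    params["nthread"] = params.get("nthread", 0) or -1
    dtrain = xgb.DMatrix(X[~tune], label=y[~tune],
                         feature_names=FEATURE_COLUMNS)
    evals, kwargs = [], {}
    if tune.any():
        dtune = xgb.DMatrix(X[tune], label=y[tune],
                            feature_names=FEATURE_COLUMNS)
        evals = [(dtune, "tune")]
        kwargs["early_stopping_rounds"] = spec.early_stopping_rounds
    booster = xgb.train(
        params, dtrain, num_boost_round=spec.n_rounds,
        evals=evals, verbose_eval=False, **kwargs,
    )
    best = getattr(booster, "best_iteration", None)
    if best is None:
        best = spec.n_rounds - 1
    return TrainedModel(booster, spec, list(FEATURE_COLUMNS), int(best))


def predict_response(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Predict on the cube-root scale."""
    d = xgb.DMatrix(
        features[FEATURE_COLUMNS].to_numpy(dtype=np.float32),
        feature_names=model.feature_names,
    )
    return model.booster.predict(
        d, iteration_range=(0, model.best_iteration + 1)
    )


def predict_nightly(
    model: TrainedModel,
    forecast_features: pd.DataFrame,
    cross_section: float = _traffic.DEFAULT_CROSS_SECTION_CM2,
    bin_height: float = _traffic.DEFAULT_BIN_HEIGHT_KM,
) -> pd.DataFrame:
    """Predict nightly traffic from forecast-channel features.

    30-min predictions are back-transformed by cubing, floored at zero
    and integrated with the same trapezoid / bin-height / cross-section
    chain as measured traffic.  Returns ``station_id``, ``night_id``,
    ``predicted_traffic`` (birds/km/night).
    """
    resp = predict_response(model, forecast_features)
    rate = np.maximum(resp, 0.0) ** 3
    df = forecast_features[KEY_COLUMNS].copy()
    # Encode the predicted rate as eta x speed with unit speed so the
    # measured-traffic integrator applies unchanged.
    df["eta_cm2_per_km3"] = rate
    df["groundspeed_kmh"] = 1.0
    nightly = _traffic.integrate_profiles(
        df, cross_section=cross_section, bin_height=bin_height
    )
    out = nightly.rename(columns={"traffic_birds_km_night": "predicted_traffic"})
    dropped = (~out["complete"]).sum()
    if dropped:
        log.warning("%d predicted nights lacked full coverage", int(dropped))
    return out[["station_id", "night_id", "predicted_traffic"]]


def save_model(model: TrainedModel, out_dir) -> None:
    """Persist the booster (XGBoost JSON) plus a manifest recording the
    hyperparameters, training years, seed and feature order."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.booster.save_model(str(out / "model.json"))
    manifest = {
        "feature_names": model.feature_names,
        "training_years": sorted(model.spec.training_years),
        "season": model.spec.season,
        "n_rounds": model.spec.n_rounds,
        "params": model.spec.params,
        "seed": model.spec.seed,
        "best_iteration": model.best_iteration,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_model(model_dir) -> TrainedModel:
    """Load a saved model; the stored feature order must match the
    package's feature contract."""
    import json
    from pathlib import Path

    d = Path(model_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest["feature_names"] != FEATURE_COLUMNS:
        raise ValidationError(
            "saved model feature order does not match this package's "
            f"contract: {manifest['feature_names']}"
        )
    booster = xgb.Booster()
    booster.load_model(str(d / "model.json"))
    spec = ForecastModelSpec(
        training_years=frozenset(manifest["training_years"]),
        season=manifest["season"], n_rounds=manifest["n_rounds"],
        params=manifest["params"], seed=manifest["seed"],
    )
    return TrainedModel(booster, spec, list(FEATURE_COLUMNS),
                        manifest["best_iteration"])


def loyo_folds(features: pd.DataFrame, years=None):
    """Yield (year, train_mask, test_mask) with a leakage assertion."""
    all_years = sorted(set(features["year"].unique().tolist()))
    years = all_years if years is None else sorted(years)
    if len(all_years) < 2:
        raise TrainingError("leave-one-year-out requires >= 2 years")
    keys = features["station_id"].astype(str) + "|" + features["night_id"].astype(str)
    for y in years:
        test = (features["year"] == y).to_numpy()
        train = ~test
        overlap = set(keys[train]) & set(keys[test])
        assert not overlap, f"leakage: {len(overlap)} station-nights shared"
        yield y, train, test


def variance_explained(obs: np.ndarray, pred: np.ndarray) -> float:
    """1 - SSE/SST against the observation mean."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    sse = float(((obs - pred) ** 2).sum())
    return 1.0 - sse / sst


def loyo_evaluate(
    features: pd.DataFrame,
    forecast_features: pd.DataFrame,
    nightly_measured: pd.DataFrame,
    season: str = "spring",
    n_rounds: int = 1000,
    early_stopping_rounds: int = 50,
    max_train_rows: int | None = None,
    seed: int = 0,
    years=None,
) -> dict:
    """Leave-one-year-out skill report.

    For each year, a model trained on all other years (reanalysis-channel
    features) predicts the held-out year from forecast-channel features.
    Skill is reported as variance explained on the cube-root 30-min scale
    plus the Pearson correlation of predicted and measured nightly
    traffic.  ``max_train_rows`` optionally subsamples the training rows
    (seeded) to bound compute.

    Returns a dict with per-year rows, the pooled means/SDs, the nightly
    prediction table for every held-out year, and per-fold key counts.
    """
    fkey = forecast_features.set_index(KEY_COLUMNS)
    rows, nightly_frames = [], []
    rng = np.random.default_rng([seed % (2**31), 90001])
    for y, train, test in loyo_folds(features, years):
        tr = features[train]
        if max_train_rows is not None and len(tr) > max_train_rows:
            idx = rng.choice(len(tr), size=max_train_rows, replace=False)
            tr = tr.iloc[np.sort(idx)]
        spec = ForecastModelSpec(
            training_years=frozenset(tr["year"].unique().tolist()),
            season=season, n_rounds=n_rounds,
            early_stopping_rounds=early_stopping_rounds, seed=seed,
        )
        model = train_seasonal_model(tr, spec)

        te = features[test]
        ff = fkey.reindex(pd.MultiIndex.from_frame(te[KEY_COLUMNS]))
        ff = ff.reset_index()
        if ff[FEATURE_COLUMNS].isna().any().any():
            raise ValidationError(
                f"forecast features missing for held-out year {y}"
            )
        pred = predict_response(model, ff)
        ve = variance_explained(te["response"].to_numpy(), pred)

        nightly_pred = predict_nightly(model, ff)
        nightly_pred["year"] = y
        nightly_frames.append(nightly_pred)
        joined = nightly_pred.merge(
            nightly_measured, on=["station_id", "night_id"], how="inner"
        )
        r = float(np.corrcoef(
            joined["predicted_traffic"], joined["traffic_birds_km_night"]
        )[0, 1]) if len(joined) > 1 else float("nan")
        rows.append({
            "year": y, "variance_explained": ve, "nightly_r": r,
            "n_train": int(len(tr)), "n_test": int(len(te)),
            "best_iteration": model.best_iteration,
        })
    report = pd.DataFrame(rows)
    return {
        "per_year": report,
        "mean_variance_explained": float(report["variance_explained"].mean()),
        "sd_variance_explained": float(report["variance_explained"].std(ddof=1))
        if len(report) > 1 else float("nan"),
        "mean_nightly_r": float(report["nightly_r"].mean()),
        "nightly_predictions": pd.concat(nightly_frames, ignore_index=True),
    }
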