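"""Feature construction, model training, back-transform chain and the
leave-one-year-out protocol."""

import numpy as np
import pandas as pd
import pytest

from aeroalert import SimulationConfig, StationConfig, TrainingError
from aeroalert import forecast, synthetic, traffic


@pytest.fixture(scope="module")
def features_small(small_config, small_dataset):
    weather, profiles, _ = small_dataset
    return forecast.build_features(profiles, weather)


def test_features_complete_and_typed(features_small, small_dataset):
    _, profiles, _ = small_dataset
    assert len(features_small) == len(profiles)
    assert list(features_small.columns[-15:-1]) == ["year"] + \
        forecast.FEATURE_COLUMNS
    assert not features_small[forecast.FEATURE_COLUMNS].isna().any().any()


def test_response_is_cube_root_of_flux():
    """eta=8, speed=27 -> response (216)^(1/3) = 6."""
    assert np.cbrt(8 * 27) == pytest.approx(6.0, rel=1e-12)


def test_hour_after_sunset_zero_at_sunset(features_small):
    at_sunset = features_small[features_small["minutes_after_sunset"] == 0]
    assert (at_sunset["hour_after_sunset"] == 0).all()


def test_nearest_weather_join_rule():
    """A sample 70 min past a weather time joins that record, not the one
    110 min later; an equidistant sample joins the earlier record."""
    snapped = forecast._nearest_weather_time(
        pd.Series(pd.to_datetime([
            "2015-04-01 01:10", "2015-04-01 01:30", "2015-04-01 01:31",
        ]))
    )
    assert list(snapped) == list(pd.to_datetime(
        ["2015-04-01 00:00", "2015-04-01 00:00", "2015-04-01 03:00"]
    ))


def test_back_transform_round_trip():
    x = np.logspace(-3, 4, 50)
    assert np.cbrt(x) ** 3 == pytest.approx(x, rel=1e-9)


def test_constant_zero_response_predicts_zero(features_small):
    feats = features_small.head(4000).copy()
    feats["response"] = 0.0
    spec = forecast.ForecastModelSpec(
        training_years=frozenset({2015}), n_rounds=20, seed=0)
    model = forecast.train_seasonal_model(feats, spec)
    pred = forecast.predict_response(model, feats)
    assert np.abs(pred).max() < 1e-6


def test_recovers_monotone_wind_signal(features_small):
    """A deterministic monotone function of vwind alone is recovered with
    held-out R^2 >= 0.95 at n = 10,000."""
    rng = np.random.default_rng(0)
    feats = features_small.sample(n=12500, random_state=1).copy()
    feats["response"] = 5.0 + 2.0 * np.tanh(feats["vwind_ms"] / 5.0)
    train, test = feats.iloc[:10000], feats.iloc[10000:]
    spec = forecast.ForecastModelSpec(
        training_years=frozenset({2015}), n_rounds=400,
        early_stopping_rounds=30, seed=0)
    model = forecast.train_seasonal_model(train, spec)
    pred = forecast.predict_response(model, test)
    r2 = forecast.variance_explained(test["response"].to_numpy(), pred)
    assert r2 >= 0.95
    # permuting a predictor absent from the generating function barely moves
    # the held-out score
    shuffled = test.copy()
    shuffled["rh_pct"] = rng.permutation(shuffled["rh_pct"].to_numpy())
    pred2 = forecast.predict_response(model, shuffled)
    r2b = forecast.variance_explained(shuffled["response"].to_numpy(), pred2)
    assert abs(r2 - r2b) < 0.02


def test_training_rejects_out_of_scope_years(features_small):
    feats = features_small.head(100)
    spec = forecast.ForecastModelSpec(training_years=frozenset({1999}),
                                      n_rounds=5)
    with pytest.raises(TrainingError):
        forecast.train_seasonal_model(feats, spec)
    with pytest.raises(TrainingError):
        forecast.train_seasonal_model(feats.head(0), spec)


def test_predict_nightly_constant_closed_form(features_small):
    """A model fitted to a constant response r yields nightly traffic
    r^3 * L * 0.1 * 30 / 11 for an L-hour fully covered night."""
    feats = features_small[features_small["night_id"] == "2015-04-15"].copy()
    r = 2.0
    feats["response"] = r
    spec = forecast.ForecastModelSpec(training_years=frozenset({2015}),
                                      n_rounds=30, seed=0)
    model = forecast.train_seasonal_model(feats, spec)
    nightly = forecast.predict_nightly(model, feats)
    expected = r**3 * 10.0 * 0.1 * 30 / 11.0
    assert len(nightly) == 1
    assert nightly["predicted_traffic"].iloc[0] == pytest.approx(
        expected, rel=0.01)


def test_identical_features_give_identical_predictions(features_small):
    feats = features_small.head(5000)
    spec = forecast.ForecastModelSpec(training_years=frozenset({2015}),
                                      n_rounds=10, seed=0)
    model = forecast.train_seasonal_model(feats, spec)
    p1 = forecast.predict_response(model, feats.head(100))
    p2 = forecast.predict_response(model, feats.head(100))
    np.testing.assert_array_equal(p1, p2)


def test_model_save_load_round_trip(features_small, tmp_path):
    feats = features_small.head(3000)
    spec = forecast.ForecastModelSpec(training_years=frozenset({2015}),
                                      n_rounds=10, seed=0)
    model = forecast.train_seasonal_model(feats, spec)
    forecast.save_model(model, tmp_path / "m")
    again = forecast.load_model(tmp_path / "m")
    np.testing.assert_allclose(
        forecast.predict_response(model, feats.head(50)),
        forecast.predict_response(again, feats.head(50)), rtol=1e-6)
    # a tampered feature order is refused
    import json
    mpath = tmp_path / "m" / "manifest.json"
    manifest = json.loads(mpath.read_text())
    manifest["feature_names"] = manifest["feature_names"][::-1]
    mpath.write_text(json.dumps(manifest))
    from aeroalert import ValidationError
    with pytest.raises(ValidationError):
        forecast.load_model(tmp_path / "m")


def test_variance_explained_reference_points():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert forecast.variance_explained(obs, obs) == 1.0
    assert forecast.variance_explained(obs, np.full(4, obs.mean())) == 0.0


def test_loyo_folds_are_leakage_free():
    feats = pd.DataFrame({
        "station_id": ["A"] * 6 + ["B"] * 6,
        "night_id": [f"201{y}-04-0{d}" for y in (4, 5, 6) for d in (1, 2)] * 2,
        "year": [2014, 2014, 2015, 2015, 2016, 2016] * 2,
    })
    seen = []
    for y, train, test in forecast.loyo_folds(feats):
        keys_train = set(zip(feats.loc[train, "station_id"],
                             feats.loc[train, "night_id"]))
        keys_test = set(zip(feats.loc[test, "station_id"],
                            feats.loc[test, "night_id"]))
        assert not keys_train & keys_test
        seen.append(y)
    assert seen == [2014, 2015, 2016]
    with pytest.raises(TrainingError):
        list(forecast.loyo_folds(feats[feats["year"] == 2014]))


def test_loyo_recovery_and_train_exceeds_holdout(one_station):
    """On a 3-year toy dataset the pipeline recovers predictive skill and
    training-year fit exceeds held-out fit.  (Two or more training years
    are needed for skill to transfer: a single year lets the deep trees
    memorise that year's pulse pattern through ordinal date.)"""
    cfg = SimulationConfig(stations=[one_station], years=[2013, 2014, 2015],
                           seed=6)
    wx = synthetic.simulate_weather(cfg)
    profiles, _ = synthetic.simulate_migration(cfg, wx)
    nightly = traffic.integrate_profiles(profiles)
    feats = forecast.build_features(profiles, wx)
    rep = forecast.loyo_evaluate(
        feats, feats, nightly, n_rounds=150, early_stopping_rounds=20,
        max_train_rows=40000, seed=0,
    )
    assert rep["mean_variance_explained"] > 0.3
    # training fit beats held-out fit for the first fold
    y0 = rep["per_year"]["year"].iloc[0]
    tr = feats[feats["year"] != y0]
    spec = forecast.ForecastModelSpec(
        training_years=frozenset(tr["year"].unique().tolist()),
        n_rounds=150, early_stopping_rounds=20, seed=0)
    model = forecast.train_seasonal_model(
        tr.sample(n=40000, random_state=0).sort_index(), spec)
    in_sample = forecast.variance_explained(
        tr["response"].to_numpy(),
        forecast.predict_response(model, tr))
    assert in_sample > rep["per_year"]["variance_explained"].iloc[0]
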