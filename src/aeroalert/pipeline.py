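"""End-to-end pipeline: simulate -> integrate -> forecast -> select -> evaluate.

Each stage writes its outputs plus a manifest (stage name, config hash,
seed, input checksums, row counts).  Re-running with the same config and
seed reproduces identical manifests for the deterministic stages; with
``resume=True`` stages whose outputs already exist under a matching
config hash are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, forecast, selection, synthetic, traffic
from .config import PipelineConfig, SimulationConfig
from .errors import AeroalertError

log = logging.getLogger(__name__)


def _hash_config(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, stage: str, cfg_hash: str, seed: int,
                    inputs: list[Path], outputs: list[Path],
                    counts: dict) -> dict:
    manifest = {
        "stage": stage,
        "config_hash": cfg_hash,
        "seed": seed,
        "inputs": {p.name: _checksum(p) for p in inputs},
        "outputs": {p.name: _checksum(p) for p in outputs},
        "counts": counts,
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_done(out: Path, stage: str, cfg_hash: str,
                outputs: list[Path]) -> bool:
    mpath = out / f"manifest_{stage}.json"
    if not mpath.exists() or not all(p.exists() for p in outputs):
        return False
    with open(mpath) as fh:
        manifest = json.load(fh)
    return manifest.get("config_hash") == cfg_hash


def build_seasons(
    nightly: pd.DataFrame, sim: SimulationConfig, min_nights: int = 100
) -> dict[tuple[str, int], traffic.SeasonSeries]:
    """Assemble one SeasonSeries per station-year from a nightly table."""
    out = {}
    years_by_night = pd.to_datetime(nightly["night_id"]).dt.year
    for st in sim.stations:
        for year in sim.years:
            sub = nightly[(nightly["station_id"] == st.station_id)
                          & (years_by_night == year)]
            out[(st.station_id, year)] = traffic.build_season(
                sub, st.station_id, sim.season, year,
                sim.season_dates(year), min_nights=min_nights,
            )
    return out


def select_all(
    seasons: dict[tuple[str, int], traffic.SeasonSeries],
    predictions: pd.DataFrame,
    sim: SimulationConfig,
    targets,
) -> list[selection.SelectionResult]:
    """Run the three selection methods for every valid station-year.

    For each evaluation year the forecast threshold and the fixed window
    are derived from all *other* valid years of the same station, using
    out-of-sample predictions throughout.
    """
    results = []
    for st in sim.stations:
        sid = st.station_id
        valid_years = [y for y in sim.years if seasons[(sid, y)].valid]
        pred_st = predictions[predictions["station_id"] == sid]
        for y in valid_years:
            derivation = {yy: seasons[(sid, yy)] for yy in valid_years
                          if yy != y}
            eval_series = seasons[(sid, y)]
            pred_eval = pred_st[pred_st["year"] == y]
            pred_deriv = pred_st[pred_st["year"] != y]
            for target in targets:
                results.append(
                    selection.idealized_dynamic(eval_series, target)
                )
                if derivation:
                    policy = selection.derive_threshold(
                        pred_deriv, derivation, target
                    )
                    results.append(selection.apply_threshold(
                        policy, pred_eval, eval_series
                    ))
                    window = selection.optimal_fixed_window(
                        derivation,
                        {yy: sim.season_dates(yy) for yy in derivation},
                        target,
                    )
                    results.append(selection.evaluate_window(
                        window, eval_series, sim.season_dates(y), target
                    ))
    return results


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int | None = None,
    resume: bool = False,
) -> dict:
    """Execute the full pipeline, returning the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if seed is not None:
        sim.seed = int(seed)
    cfg_hash = _hash_config(config)
    manifests = {}

    # -- simulate ------------------------------------------------------
    data_files = [out / n for n in (
        "weather.csv", "forecast_weather.csv", "profiles.csv", "truth.csv")]
    if resume and _stage_done(out, "simulate", cfg_hash, data_files):
        log.info("simulate: outputs present, skipping")
    else:
        synthetic.generate_dataset(sim, out)
        _write_manifest(out, "simulate", cfg_hash, sim.seed, [], data_files,
                        {})
    manifests["simulate"] = True

    # -- integrate -----------------------------------------------------
    nightly_path = out / "nightly.csv"
    if resume and _stage_done(out, "integrate", cfg_hash, [nightly_path]):
        nightly = pd.read_csv(nightly_path)
    else:
        profiles = pd.read_csv(out / "profiles.csv")
        nightly = traffic.integrate_profiles(
            profiles,
            cross_section=config.cross_section_cm2,
            bin_height=config.bin_height_km,
        )
        nightly.to_csv(nightly_path, index=False)
        _write_manifest(out, "integrate", cfg_hash, sim.seed,
                        [out / "profiles.csv"], [nightly_path],
                        {"nights": len(nightly)})
    manifests["integrate"] = True

    # -- forecast ------------------------------------------------------
    pred_path = out / "predictions.csv"
    skill_path = out / "skill.json"
    if resume and _stage_done(out, "forecast", cfg_hash,
                              [pred_path, skill_path]):
        predictions = pd.read_csv(pred_path)
        with open(skill_path) as fh:
            skill = json.load(fh)
    else:
        profiles = pd.read_csv(out / "profiles.csv")
        weather = pd.read_csv(out / "weather.csv",
                              parse_dates=["timestamp_utc"])
        fweather = pd.read_csv(out / "forecast_weather.csv",
                               parse_dates=["timestamp_utc"])
        feats = forecast.build_features(profiles, weather)
        ffeats = forecast.build_features(profiles, fweather)
        report = forecast.loyo_evaluate(
            feats, ffeats, nightly,
            season=sim.season,
            n_rounds=config.n_rounds,
            early_stopping_rounds=config.early_stopping_rounds,
            max_train_rows=config.max_train_rows,
            seed=sim.seed,
        )
        predictions = report["nightly_predictions"]
        predictions.to_csv(pred_path, index=False)
        skill = {
            "mean_variance_explained": report["mean_variance_explained"],
            "sd_variance_explained": report["sd_variance_explained"],
            "mean_nightly_r": report["mean_nightly_r"],
            "per_year": report["per_year"].to_dict(orient="records"),
        }
        with open(skill_path, "w") as fh:
            json.dump(skill, fh, indent=2, sort_keys=True)
        _write_manifest(out, "forecast", cfg_hash, sim.seed,
                        [out / "profiles.csv", out / "weather.csv"],
                        [pred_path, skill_path],
                        {"predicted_nights": len(predictions)})
    manifests["forecast"] = True

    # -- select --------------------------------------------------------
    results_path = out / "selections.csv"
    if resume and _stage_done(out, "select", cfg_hash, [results_path]):
        results_df = pd.read_csv(results_path)
    else:
        seasons = build_seasons(nightly, sim, config.min_valid_nights)
        targets = sorted(set(config.target_fractions)
                         | set(config.exploration_grid))
        results = select_all(seasons, predictions, sim, targets)
        results_df = selection.results_table(results)
        results_df.to_csv(results_path, index=False)
        _write_manifest(out, "select", cfg_hash, sim.seed,
                        [nightly_path, pred_path], [results_path],
                        {"selections": len(results_df)})
    manifests["select"] = True

    # -- evaluate ------------------------------------------------------
    conc_path = out / "concentration.csv"
    curve_path = out / "capture_curve.csv"
    summary_path = out / "summary.json"
    if resume and _stage_done(out, "evaluate", cfg_hash,
                              [conc_path, curve_path, summary_path]):
        with open(summary_path) as fh:
            summary = json.load(fh)
    else:
        seasons = build_seasons(nightly, sim, config.min_valid_nights)
        valid = [s for s in seasons.values() if s.valid]
        conc = evaluation.concentration_table(valid)
        conc.to_csv(conc_path, index=False)
        curve = evaluation.capture_curve(results_df)
        curve.to_csv(curve_path, index=False)
        stations_df = pd.DataFrame(
            [{"station_id": s.station_id, "latitude": s.latitude,
              "longitude": s.longitude} for s in sim.stations]
        )
        summary = {"skill": skill, "comparisons": {}}
        at_half = results_df[np.isclose(results_df["target_fraction"], 0.5)]
        for pair in (("idealized_dynamic", "forecast_dynamic"),
                     ("forecast_dynamic", "fixed_window"),
                     ("idealized_dynamic", "fixed_window")):
            try:
                cmp = evaluation.compare_methods(
                    at_half, pair[0], pair[1],
                    stations=stations_df if len(stations_df) >= 3 else None,
                )
            except AeroalertError as exc:
                cmp = {"error": str(exc)}
            summary["comparisons"][f"{pair[1]}_minus_{pair[0]}"] = cmp
        top10 = conc[np.isclose(conc["fraction"], 0.10)]["share"]
        if len(top10):
            summary["top10_share_mean"] = float(top10.mean())
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        _write_manifest(out, "evaluate", cfg_hash, sim.seed,
                        [results_path], [conc_path, curve_path, summary_path],
                        {"concentration_rows": len(conc)})
    manifests["evaluate"] = True

    run_manifest = {
        "config_hash": cfg_hash,
        "seed": sim.seed,
        "stages": sorted(manifests),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest_run.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return run_manifest
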