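"""Synthetic radar-like migration profiles and matched weather covariates.

The generator emulates the statistical structure of processed
weather-surveillance-radar migration data: strongly pulsed night-to-night
passage driven by synoptic weather, a seasonal phenology envelope,
exponential decay of activity with altitude, a unimodal within-night
activity curve sampled every 30 min, and multiplicative observation
noise.  Everything is a pure function of (config, seed).

Conventions
-----------
* A night is labelled by the local calendar date of sunset; post-midnight
  samples carry that night's label.
* Sunset is fixed at 19:00 local solar time, where the local solar offset
  is ``longitude / 15`` hours; no ephemeris is computed.
* Weather lives on a 3-h UTC grid at 100-m heights 0–3000 m, covering
  every season date plus the following day (nights run past midnight, so
  the final night needs next-day records).
* Activity profiles live on 100-m bins 0–2900 m (bin lower edge) and a
  30-min grid from sunset to sunrise inclusive.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    PROFILE_BINS_M,
    PROFILE_STEP_MIN,
    WEATHER_HEIGHTS_M,
    WEATHER_STEP_H,
    SimulationConfig,
    StationConfig,
)
from .errors import ConfigurationError, GenerationError

#: Constant airspeed added to the tailwind component, km/h (≈12 m/s).
AIRSPEED_KMH = 43.2

#: Floor applied to simulated groundspeed, km/h.
MIN_GROUNDSPEED_KMH = 1.0

WEATHER_COLUMNS = [
    "station_id", "timestamp_utc", "height_m", "uwind_ms", "vwind_ms",
    "temp_c", "sp_pa", "rh_pct", "tcc_pct", "vis_m", "mslp_pa",
]

PROFILE_COLUMNS = [
    "station_id", "latitude", "longitude", "night_id", "minutes_after_sunset",
    "height_bin_m", "eta_cm2_per_km3", "groundspeed_kmh", "direction_deg",
]

TRUTH_COLUMNS = ["station_id", "night_id", "latent_total", "favorability"]


def sunset_utc(station: StationConfig, night: dt.date) -> pd.Timestamp:
    """UTC time of sunset for the night labelled ``night``.

    Sunset is 19:00 local solar time; for US longitudes this lands between
    ~23:20 UTC on the label date and ~03:20 UTC the next day.
    """
    offset_h = 19.0 - station.longitude / 15.0
    return pd.Timestamp(night) + pd.Timedelta(hours=offset_h)


def migration_heading_deg(season: str) -> float:
    """Seasonal mean migration heading: north in spring, south in autumn."""
    return 0.0 if season == "spring" else 180.0


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance."""
    eps = rng.standard_normal(n)
    s = np.empty(n)
    s[0] = eps[0]
    scale = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        s[i] = rho * s[i - 1] + scale * eps[i]
    return s


def _station_rng(config: SimulationConfig, si: int, year: int, stream: int):
    return np.random.default_rng(
        [config.seed % (2**31), 7919, si, year % 10000, stream]
    )


# ---------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------

def simulate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the reanalysis weather table for every station-year.

    Winds follow a nightly AR(1) synoptic driver (coefficient
    ``weather_ar1_rho``) shared across the night's 3-h timestamps, plus a
    height-dependent shear term and small within-night noise.  Bounded
    fields (humidity, cloud cover) are clipped into their physical ranges.
    """
    config.validate()
    heights = np.asarray(WEATHER_HEIGHTS_M, dtype=float)
    nh = heights.size
    hfrac = heights / 3000.0
    frames = []
    for si, st in enumerate(config.stations):
        for year in config.years:
            nights = config.season_dates(year)
            n = len(nights)
            # 3-h UTC grid over every season date plus one trailing day.
            n_days = n + 1
            t0 = pd.Timestamp(nights[0])
            ts = t0 + pd.to_timedelta(
                np.arange(n_days * 24 // WEATHER_STEP_H) * WEATHER_STEP_H, unit="h"
            )
            nt = ts.size
            sunsets = np.array(
                [sunset_utc(st, d).value for d in nights], dtype="int64"
            )
            # Each timestamp is driven by the most recently begun night.
            nidx = np.clip(
                np.searchsorted(sunsets, ts.asi8, side="right") - 1, 0, n - 1
            )

            rho = config.weather_ar1_rho
            sv = _ar1(_station_rng(config, si, year, 1), n, rho)
            su = _ar1(_station_rng(config, si, year, 2), n, rho)
            sp = _ar1(_station_rng(config, si, year, 3), n, rho)
            srh = _ar1(_station_rng(config, si, year, 4), n, rho)
            scl = _ar1(_station_rng(config, si, year, 5), n, rho)
            rng = _station_rng(config, si, year, 9)

            vw = 5.0 * sv[nidx][:, None] + 3.0 * hfrac[None, :] \
                + rng.normal(0.0, 1.0, (nt, nh))
            uw = 4.0 * su[nidx][:, None] + 2.0 * hfrac[None, :] \
                + rng.normal(0.0, 1.0, (nt, nh))

            # Seasonal temperature ramp by night index, lapse with height.
            prog = nidx / max(n - 1, 1)
            t_sfc = 8.0 + 12.0 * prog if config.season == "spring" \
                else 26.0 - 14.0 * prog
            temp = t_sfc[:, None] - 6.5 * (heights / 1000.0)[None, :] \
                + rng.normal(0.0, 1.5, (nt, nh))

            sp_pa = 98000.0 + 300.0 * sp[nidx] + rng.normal(0.0, 50.0, nt)
            mslp = 101325.0 + 400.0 * sp[nidx] + rng.normal(0.0, 60.0, nt)
            rh = np.clip(
                60.0 + 18.0 * srh[nidx][:, None] + rng.normal(0.0, 6.0, (nt, nh)),
                0.0, 100.0,
            )
            tcc = np.clip(
                45.0 + 35.0 * scl[nidx][:, None] + rng.normal(0.0, 10.0, (nt, nh)),
                0.0, 100.0,
            )
            vis = np.clip(
                20000.0 - 120.0 * tcc + rng.normal(0.0, 1500.0, (nt, nh)),
                50.0, None,
            )

            frames.append(pd.DataFrame({
                "station_id": st.station_id,
                "timestamp_utc": np.repeat(ts.values, nh),
                "height_m": np.tile(heights, nt),
                "uwind_ms": uw.ravel(),
                "vwind_ms": vw.ravel(),
                "temp_c": temp.ravel(),
                "sp_pa": np.repeat(sp_pa, nh),
                "rh_pct": rh.ravel(),
                "tcc_pct": tcc.ravel(),
                "vis_m": vis.ravel(),
                "mslp_pa": np.repeat(mslp, nh),
            }))
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["station_id", "timestamp_utc", "height_m"],
                    inplace=True, kind="mergesort", ignore_index=True)
    return out


def make_forecast_weather(
    weather: pd.DataFrame, error_sd: float, seed: int
) -> pd.DataFrame:
    """Forecast-weather channel: reanalysis plus Gaussian error.

    ``error_sd`` is a relative scale: each perturbed field receives
    independent Gaussian noise with SD equal to ``error_sd`` times that
    field's marginal SD across all records.  ``error_sd = 0`` returns the
    idealized limit (a copy of the reanalysis table).  Wind components
    and temperature — the fields that drive simulated migration — are
    perturbed; bounded fields are re-clipped.
    """
    out = weather.copy()
    if error_sd == 0:
        return out
    rng = np.random.default_rng([seed % (2**31), 104729])
    for col in ("uwind_ms", "vwind_ms", "temp_c"):
        sd = float(out[col].std())
        out[col] = out[col] + rng.normal(0.0, error_sd * sd, len(out))
    return out


# ---------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------

def _night_weather_stats(
    st: StationConfig,
    season: str,
    nights: list[dt.date],
    wx: pd.DataFrame,
    bins: np.ndarray,
):
    """Per-night mean tailwind overall and per height bin.

    Returns (favorability_raw, tail_by_bin) where ``favorability_raw`` is
    the nightly mean tailwind component in m/s (sign follows the seasonal
    heading) and ``tail_by_bin`` is a (n_nights, n_bins) array of nightly
    mean tailwind at each profile height bin.
    """
    sign = 1.0 if season == "spring" else -1.0
    t = wx["timestamp_utc"].values.astype("datetime64[ns]").astype("int64")
    h = wx["height_m"].to_numpy()
    v = wx["vwind_ms"].to_numpy()
    n = len(nights)
    sunsets = np.array([sunset_utc(st, d).value for d in nights], dtype="int64")
    length_ns = int(st.night_length * 3600 * 1e9)
    nidx = np.clip(np.searchsorted(sunsets, t, side="right") - 1, 0, n - 1)
    within = (t >= sunsets[nidx]) & (t <= sunsets[nidx] + length_ns)

    hsel = within & np.isin(h, bins)
    ni, hi, vi = nidx[hsel], h[hsel], v[hsel]
    # accumulate sums and counts per (night, bin)
    jdx = np.searchsorted(bins, hi)
    flat = ni * bins.size + jdx
    sums = np.bincount(flat, weights=vi, minlength=n * bins.size)
    cnts = np.bincount(flat, minlength=n * bins.size)
    if (cnts.reshape(n, bins.size).sum(axis=1) == 0).any():
        bad = int(np.flatnonzero(cnts.reshape(n, bins.size).sum(axis=1) == 0)[0])
        raise GenerationError(
            f"no weather records cover night {nights[bad].isoformat()} "
            f"at station {st.station_id}"
        )
    if (cnts == 0).any():
        k = int(np.flatnonzero(cnts == 0)[0])
        raise GenerationError(
            f"no weather at height {bins[k % bins.size]:.0f} m for night "
            f"{nights[k // bins.size].isoformat()} at station {st.station_id}"
        )
    tail = sign * (sums / cnts).reshape(n, bins.size)
    fav_cnt = np.bincount(nidx[within], minlength=n)
    fav = sign * np.bincount(nidx[within], weights=v[within], minlength=n) / fav_cnt
    return fav, tail


def night_shape(minutes: np.ndarray, night_length_h: float) -> np.ndarray:
    """Unimodal within-night activity density, per hour.

    Beta(2, 3)-shaped: zero at sunset and sunrise, peak at 1/3 of the
    night (first half), unit integral over the night in hours.
    """
    x = minutes / (60.0 * night_length_h)
    return 12.0 * x * (1.0 - x) ** 2 / night_length_h


def simulate_migration(
    config: SimulationConfig, weather: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate activity profiles given a weather table.

    Latent nightly intensity combines a Gaussian phenology envelope with a
    log-linear weather pulse (see :class:`SimulationConfig`).  The
    within-night curve and altitude profile distribute each night's
    intensity over the 30-min × 100-m grid; observed reflectivity is the
    latent rate divided by simulated groundspeed times log-normal
    observation noise.  Nights drop out independently with probability
    ``dropout_rate``.  Truth records keep every night's latent total and
    favorability, including dropped nights.
    """
    config.validate()
    bins = np.asarray(PROFILE_BINS_M, dtype=float)
    nb = bins.size
    p_bin = np.exp(-bins / config.altitude_scale)
    p_bin /= p_bin.sum()
    heading = migration_heading_deg(config.season)

    prof_frames, truth_frames = [], []
    for si, st in enumerate(config.stations):
        n_steps = int(st.night_length * 60 / PROFILE_STEP_MIN) + 1
        minutes = np.arange(n_steps) * PROFILE_STEP_MIN
        w = night_shape(minutes.astype(float), st.night_length)
        wx_st = weather[weather["station_id"] == st.station_id]
        for year in config.years:
            nights = config.season_dates(year)
            n = len(nights)
            fav_raw, tail = _night_weather_stats(
                st, config.season, nights, wx_st, bins
            )
            sd = fav_raw.std()
            fav = (fav_raw - fav_raw.mean()) / sd if sd > 0 else np.zeros(n)

            ords = np.array([d.timetuple().tm_yday for d in nights], dtype=float)
            mu = config.peak_ordinal(year)
            envelope = config.envelope_amplitude * np.exp(
                -((ords - mu) ** 2) / (2.0 * config.phenology_sd**2)
            )

            rng = _station_rng(config, si, year, 21)
            z = rng.standard_normal(n)
            latent = envelope * np.exp(
                config.pulse_beta * fav + config.pulse_sigma * z
            )

            speed = np.maximum(AIRSPEED_KMH + 3.6 * tail, MIN_GROUNDSPEED_KMH)
            direction = np.mod(
                heading + rng.normal(0.0, 20.0, n), 360.0
            )

            # rate[night, t, bin] in cm^2/km^2/h; eta = rate / speed.
            rate = latent[:, None, None] * w[None, :, None] * p_bin[None, None, :]
            eta = rate / speed[:, None, :]
            if config.obs_sigma > 0:
                eta = eta * np.exp(
                    config.obs_sigma * rng.standard_normal(eta.shape)
                )

            keep = rng.random(n) >= config.dropout_rate
            kept = np.flatnonzero(keep)
            night_ids = np.array([d.isoformat() for d in nights])

            nk = kept.size
            prof_frames.append(pd.DataFrame({
                "station_id": st.station_id,
                "latitude": st.latitude,
                "longitude": st.longitude,
                "night_id": np.repeat(night_ids[kept], n_steps * nb),
                "minutes_after_sunset": np.tile(
                    np.repeat(minutes, nb), nk
                ),
                "height_bin_m": np.tile(bins.astype(int), nk * n_steps),
                "eta_cm2_per_km3": eta[kept].ravel(),
                "groundspeed_kmh": np.tile(
                    speed[kept][:, None, :], (1, n_steps, 1)
                ).ravel(),
                "direction_deg": np.repeat(direction[kept], n_steps * nb),
            }))
            truth_frames.append(pd.DataFrame({
                "station_id": st.station_id,
                "night_id": night_ids,
                "latent_total": latent,
                "favorability": fav,
            }))

    profiles = pd.concat(prof_frames, ignore_index=True)
    profiles.sort_values(
        ["station_id", "night_id", "minutes_after_sunset", "height_bin_m"],
        inplace=True, kind="mergesort", ignore_index=True,
    )
    truth = pd.concat(truth_frames, ignore_index=True)
    truth.sort_values(["station_id", "night_id"], inplace=True,
                      kind="mergesort", ignore_index=True)
    return profiles, truth


# ---------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------

def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def generate_dataset(config: SimulationConfig, output_dir: str | Path) -> dict:
    """Write weather, forecast-weather, profile and truth tables plus a
    manifest to ``output_dir``.  Re-running with the same config and seed
    reproduces byte-identical files."""
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise GenerationError(f"cannot create output dir {out}: {exc}") from exc

    weather = simulate_weather(config)
    fweather = make_forecast_weather(
        weather, config.forecast_error_sd, config.seed
    )
    profiles, truth = simulate_migration(config, weather)

    paths = {
        "weather": out / "weather.csv",
        "forecast_weather": out / "forecast_weather.csv",
        "profiles": out / "profiles.csv",
        "truth": out / "truth.csv",
    }
    weather.to_csv(paths["weather"], index=False)
    fweather.to_csv(paths["forecast_weather"], index=False)
    profiles.to_csv(paths["profiles"], index=False)
    truth.to_csv(paths["truth"], index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "files": {k: p.name for k, p in paths.items()},
        "checksums": {k: _file_checksum(p) for k, p in paths.items()},
        "rows": {
            "weather": len(weather),
            "forecast_weather": len(fweather),
            "profiles": len(profiles),
            "truth": len(truth),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_manifest(path: str | Path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)
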