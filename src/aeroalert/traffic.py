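"""Nightly migration-traffic integration.

Converts 30-min, altitude-binned activity profiles into a nightly
station traffic rate.  The unit chain is kept explicit throughout:

    eta (cm^2/km^3) x groundspeed (km/h)      -> rate, cm^2/km^2/h
    trapezoid over the night (hours)          -> cm^2/km^2/night per bin
    x bin height (0.1 km)                     -> cm^2/km/night per bin
    sum over height bins                      -> cm^2/km/night
    / radar cross-section (11 cm^2 per bird)  -> birds/km/night

The cross-section default of 11 cm^2 represents an average-sized
nocturnal migrant.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_CROSS_SECTION_CM2 = 11.0
DEFAULT_BIN_HEIGHT_KM = 0.1

#: Nominal sampling interval within a night, minutes.
NOMINAL_STEP_MIN = 30

#: A night missing more than this fraction of expected steps is incomplete.
MAX_MISSING_FRACTION = 0.25


@dataclass(frozen=True)
class NightlyTraffic:
    """Integrated passage for one station-night, birds/km/night.

    ``traffic`` is NaN when the night has fewer than two time steps and
    integration is undefined (not zero).
    """

    station_id: str
    night_id: str
    traffic: float
    n_samples: int
    complete: bool


@dataclass
class SeasonSeries:
    """All nights of one station x season x year.

    ``nights`` holds one row per complete night (columns ``night_id``,
    ``traffic``); ``valid`` applies the >=100-night season filter;
    ``total_passage`` sums the complete nights.
    """

    station_id: str
    season: str
    year: int
    nights: pd.DataFrame
    total_passage: float
    valid: bool


def bin_rate(eta: float, groundspeed: float) -> float:
    """Activity flux for one sample: eta x groundspeed, cm^2/km^2/h."""
    if not np.isfinite(eta) or not np.isfinite(groundspeed):
        raise ValidationError("eta and groundspeed must be finite")
    if eta < 0 or groundspeed < 0:
        raise ValidationError("eta and groundspeed must be non-negative")
    return eta * groundspeed


def _trapezoid(hours: np.ndarray, rates: np.ndarray,
               interpolate_gaps: bool) -> float:
    """Area under the rate-vs-time curve for one height bin.

    With ``interpolate_gaps`` a single trapezoid bridges any interior gap;
    otherwise only consecutive samples at the nominal 30-min spacing
    contribute.
    """
    if hours.size < 2:
        return 0.0
    if interpolate_gaps:
        return float(np.trapezoid(rates, hours))
    dh = np.diff(hours)
    ok = dh <= NOMINAL_STEP_MIN / 60.0 + 1e-9
    areas = 0.5 * (rates[1:] + rates[:-1]) * dh
    return float(areas[ok].sum())


def integrate_night(
    samples: pd.DataFrame,
    cross_section: float = DEFAULT_CROSS_SECTION_CM2,
    bin_height: float = DEFAULT_BIN_HEIGHT_KM,
    interpolate_gaps: bool = True,
    expected_steps: int | None = None,
) -> NightlyTraffic:
    """Integrate one station-night of profile samples.

    ``samples`` must contain columns ``minutes_after_sunset``,
    ``height_bin_m``, ``eta_cm2_per_km3`` and ``groundspeed_kmh`` for a
    single (station, night).  Time steps present in some height bins but
    missing in others are treated as missing for those bins only.
    """
    df = samples
    rate = _validated_rates(df)
    return _integrate_rate_night(
        df, rate, cross_section, bin_height, interpolate_gaps, expected_steps
    )


def _validated_rates(df: pd.DataFrame) -> np.ndarray:
    eta = df["eta_cm2_per_km3"].to_numpy(dtype=float)
    speed = df["groundspeed_kmh"].to_numpy(dtype=float)
    if not np.isfinite(eta).all() or not np.isfinite(speed).all():
        raise ValidationError("non-finite eta or groundspeed")
    if (eta < 0).any() or (speed < 0).any():
        raise ValidationError("negative eta or groundspeed")
    return eta * speed


def _integrate_rate_night(
    df: pd.DataFrame,
    rate: np.ndarray,
    cross_section: float,
    bin_height: float,
    interpolate_gaps: bool,
    expected_steps: int | None,
) -> NightlyTraffic:
    if cross_section <= 0 or bin_height <= 0:
        raise ValidationError("cross_section and bin_height must be > 0")
    minutes = df["minutes_after_sunset"].to_numpy(dtype=float)
    bins = df["height_bin_m"].to_numpy()
    keys = np.stack([bins, minutes], axis=1)
    if len(np.unique(keys, axis=0)) != len(keys):
        raise ValidationError("duplicate (minutes, height_bin) sample")

    station = str(df["station_id"].iloc[0]) if "station_id" in df else ""
    night = str(df["night_id"].iloc[0]) if "night_id" in df else ""

    steps = np.unique(minutes)
    n_samples = steps.size
    if n_samples < 2:
        return NightlyTraffic(station, night, float("nan"), int(n_samples), False)

    if expected_steps is None:
        expected = int(round((steps.max() - steps.min()) / NOMINAL_STEP_MIN)) + 1
    else:
        expected = int(expected_steps)
    complete = (expected - n_samples) <= MAX_MISSING_FRACTION * expected

    total_area = 0.0
    order = np.lexsort((minutes, bins))
    b_sorted = bins[order]
    m_sorted = minutes[order] / 60.0
    r_sorted = rate[order]
    edges = np.flatnonzero(np.diff(b_sorted)) + 1
    for lo, hi in zip(np.r_[0, edges], np.r_[edges, b_sorted.size]):
        total_area += _trapezoid(
            m_sorted[lo:hi], r_sorted[lo:hi], interpolate_gaps
        )
    traffic = total_area * bin_height / cross_section
    return NightlyTraffic(station, night, float(traffic), int(n_samples), bool(complete))


def integrate_profiles(
    profiles: pd.DataFrame,
    cross_section: float = DEFAULT_CROSS_SECTION_CM2,
    bin_height: float = DEFAULT_BIN_HEIGHT_KM,
    interpolate_gaps: bool = True,
    expected_steps: int | None = None,
) -> pd.DataFrame:
    """Integrate every station-night in a profiles table.

    Returns the nightly table with columns ``station_id``, ``night_id``,
    ``traffic_birds_km_night``, ``n_samples``, ``complete``.
    """
    rows = []
    for (station, night), grp in profiles.groupby(
        ["station_id", "night_id"], sort=True
    ):
        nt = integrate_night(
            grp, cross_section, bin_height, interpolate_gaps, expected_steps
        )
        rows.append((station, night, nt.traffic, nt.n_samples, nt.complete))
    return pd.DataFrame(
        rows,
        columns=["station_id", "night_id", "traffic_birds_km_night",
                 "n_samples", "complete"],
    )


def build_season(
    nights: pd.DataFrame,
    station_id: str,
    season: str,
    year: int,
    season_dates: list[dt.date],
    min_nights: int = 100,
) -> SeasonSeries:
    """Assemble a season series and apply the >=min_nights validity filter.

    ``nights`` is a nightly table (as produced by
    :func:`integrate_profiles`) restricted to one station; incomplete
    nights are excluded from both the night count and the total.
    """
    allowed = {d.isoformat() for d in season_dates}
    df = nights.loc[nights["station_id"] == station_id].copy()
    bad = set(df["night_id"]) - allowed
    if bad:
        raise ValidationError(
            f"night {sorted(bad)[0]} outside season bounds for {station_id}"
        )
    df = df[df["complete"] & df["traffic_birds_km_night"].notna()]
    df = df.sort_values("night_id", ignore_index=True)
    out = df[["night_id", "traffic_birds_km_night"]].rename(
        columns={"traffic_birds_km_night": "traffic"}
    )
    total = float(out["traffic"].sum())
    return SeasonSeries(
        station_id=station_id,
        season=season,
        year=year,
        nights=out,
        total_passage=total,
        valid=len(out) >= min_nights,
    )
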