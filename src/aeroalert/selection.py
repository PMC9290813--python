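"""Action-night selection strategies.

Three ways to pick the nights on which to trigger a mitigation measure
(lights-out, turbine curtailment) so that a target fraction of a
season's migratory passage is protected:

* **idealized dynamic** — with perfect hindsight, the minimum set of
  nights capturing the target fraction of measured passage (top-k by
  traffic, which is provably minimal for this objective);
* **forecast dynamic** — a traffic threshold on the *predicted* scale,
  derived from past years, triggers action nights in the year of
  interest; capture is always scored against measured passage;
* **fixed window** — a static calendar window, chosen from past years by
  exhaustive search over widths 1–100 and all feasible starts.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SelectionError, ValidationError
from .traffic import SeasonSeries

log = logging.getLogger(__name__)

MAX_WINDOW_NIGHTS = 100


@dataclass
class SelectionResult:
    """An action-night set from one method, scored against measurement."""

    method: str
    station_id: str
    season: str
    year: int
    action_nights: frozenset
    n_nights: int
    capture_fraction: float
    target_fraction: float
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ThresholdPolicy:
    """A predicted-scale trigger threshold derived from past years."""

    target_fraction: float
    threshold: float
    derivation_years: frozenset
    feasible: bool = True


@dataclass(frozen=True)
class FixedWindow:
    """A static seasonal window [start_index, start_index + width).

    ``start_index`` counts nights from the season's first calendar date,
    so the same window recurs every year; ``start_month_day`` is the
    human-readable "MM-DD" of the start night.
    """

    start_index: int
    width: int
    mean_capture: float
    start_month_day: str = ""
    feasible: bool = True


def _series_arrays(series: SeasonSeries):
    nights = series.nights["night_id"].to_numpy()
    traffic = series.nights["traffic"].to_numpy(dtype=float)
    return nights, traffic


def idealized_dynamic(
    series: SeasonSeries, target_fraction: float
) -> SelectionResult:
    """Minimum night set capturing ``target_fraction`` with hindsight.

    Nights are ranked by measured traffic (descending, ties broken by
    earlier date) and the shortest prefix reaching the target is
    returned; ranking by value makes this prefix the minimum-cardinality
    subset.
    """
    if not 0 < target_fraction <= 1:
        raise SelectionError("target_fraction must lie in (0, 1]")
    nights, traffic = _series_arrays(series)
    total = traffic.sum()
    if total <= 0:
        raise SelectionError(
            f"total passage is zero for {series.station_id} {series.year}"
        )
    order = np.lexsort((nights, -traffic))
    cum = np.cumsum(traffic[order])
    k = int(np.searchsorted(cum, target_fraction * total - 1e-12) + 1)
    chosen = nights[order[:k]]
    span = None
    if k:
        span = (pd.to_datetime(chosen.max()) - pd.to_datetime(chosen.min())).days + 1
    return SelectionResult(
        method="idealized_dynamic",
        station_id=series.station_id,
        season=series.season,
        year=series.year,
        action_nights=frozenset(chosen.tolist()),
        n_nights=k,
        capture_fraction=float(cum[k - 1] / total),
        target_fraction=float(target_fraction),
        detail={"span_nights": span},
    )


def derive_threshold(
    predicted: pd.DataFrame,
    measured: dict[int, SeasonSeries],
    target_fraction: float,
    pooling: str = "pooled",
) -> ThresholdPolicy:
    """Find the trigger threshold from derivation years.

    ``predicted`` holds columns ``year``, ``night_id``,
    ``predicted_traffic`` for one station over the derivation years;
    ``measured`` maps each of those years to its measured season.
    Candidate thresholds are the distinct predicted nightly values; the
    policy keeps the largest threshold t such that nights with predicted
    traffic >= t capture at least the target fraction of measured
    passage (equivalently, the fewest action nights meeting the target).
    Predictions gate the selection; measured passage scores it, so the
    rule is robust to miscalibrated prediction magnitudes.

    ``pooling='pooled'`` scores capture as summed captured traffic over
    summed totals across years; ``'per_year'`` averages per-year capture
    fractions instead.
    """
    if not 0 < target_fraction <= 1:
        raise SelectionError("target_fraction must lie in (0, 1]")
    if pooling not in ("pooled", "per_year"):
        raise SelectionError(f"unknown pooling {pooling!r}")
    years = sorted(measured)
    if not years:
        raise SelectionError("derivation years are empty")
    frames = []
    for y in years:
        nights, traffic = _series_arrays(measured[y])
        m = pd.DataFrame({"night_id": nights, "measured": traffic, "year": y})
        p = predicted.loc[predicted["year"] == y,
                          ["night_id", "predicted_traffic"]]
        j = m.merge(p, on="night_id", how="left")
        miss = j["predicted_traffic"].isna()
        if miss.any():
            log.warning("%d measured nights of %s lack predictions",
                        int(miss.sum()), y)
            # Unpredicted nights can never be selected by a threshold.
            j.loc[miss, "predicted_traffic"] = -np.inf
        frames.append(j)
    df = pd.concat(frames, ignore_index=True)

    cands = np.unique(df["predicted_traffic"].to_numpy())
    cands = cands[np.isfinite(cands)][::-1]  # descending
    if cands.size == 0:
        raise SelectionError("no finite predicted values to derive from")

    pred = df["predicted_traffic"].to_numpy()
    meas = df["measured"].to_numpy()
    yr = df["year"].to_numpy()
    totals = {y: meas[yr == y].sum() for y in years}
    if pooling == "pooled" and sum(totals.values()) <= 0:
        raise SelectionError("total measured passage is zero")

    for t in cands:
        sel = pred >= t
        if pooling == "pooled":
            capture = meas[sel].sum() / sum(totals.values())
        else:
            caps = [meas[sel & (yr == y)].sum() / totals[y]
                    for y in years if totals[y] > 0]
            capture = float(np.mean(caps)) if caps else 0.0
        if capture >= target_fraction - 1e-12:
            return ThresholdPolicy(
                target_fraction=float(target_fraction),
                threshold=float(t),
                derivation_years=frozenset(years),
            )
    log.warning("no threshold achieves target %.2f; falling back to the "
                "smallest candidate", target_fraction)
    return ThresholdPolicy(
        target_fraction=float(target_fraction),
        threshold=float(cands[-1]),
        derivation_years=frozenset(years),
        feasible=False,
    )


def apply_threshold(
    policy: ThresholdPolicy,
    predicted: pd.DataFrame,
    measured: SeasonSeries,
    enforce_holdout: bool = True,
) -> SelectionResult:
    """Apply a derived threshold to the evaluation year.

    ``predicted`` holds ``night_id`` and ``predicted_traffic`` for the
    evaluation year.  Nights with a measured value but no prediction are
    treated as below threshold (logged).  No re-optimization happens on
    the evaluation year.  ``enforce_holdout=False`` permits scoring a
    threshold on its own derivation year (used by the perfect-forecast
    consistency check).
    """
    if enforce_holdout and measured.year in policy.derivation_years:
        raise ValidationError(
            f"evaluation year {measured.year} is in the derivation years"
        )
    nights, traffic = _series_arrays(measured)
    m = pd.DataFrame({"night_id": nights, "measured": traffic})
    j = m.merge(predicted[["night_id", "predicted_traffic"]],
                on="night_id", how="left")
    miss = j["predicted_traffic"].isna()
    if miss.any():
        log.warning("%d measured nights lack predictions; treated as "
                    "below threshold", int(miss.sum()))
        j.loc[miss, "predicted_traffic"] = -np.inf
    sel = j["predicted_traffic"].to_numpy() >= policy.threshold
    total = j["measured"].sum()
    capture = float(j.loc[sel, "measured"].sum() / total) if total > 0 else 0.0
    chosen = j.loc[sel, "night_id"]
    return SelectionResult(
        method="forecast_dynamic",
        station_id=measured.station_id,
        season=measured.season,
        year=measured.year,
        action_nights=frozenset(chosen.tolist()),
        n_nights=int(sel.sum()),
        capture_fraction=capture,
        target_fraction=policy.target_fraction,
        detail={"threshold": policy.threshold,
                "threshold_feasible": policy.feasible},
    )


def _season_positions(
    series: SeasonSeries, season_dates: dict[int, list[dt.date]]
) -> np.ndarray:
    """Per-season-night traffic vector for one series, zeros where missing."""
    dates = season_dates[series.year]
    pos = {d.isoformat(): i for i, d in enumerate(dates)}
    arr = np.zeros(len(dates))
    nights, traffic = _series_arrays(series)
    for night, t in zip(nights, traffic):
        try:
            arr[pos[str(night)]] = t
        except KeyError:
            raise ValidationError(
                f"night {night} outside season bounds for year {series.year}"
            ) from None
    return arr


def _window_captures(
    series_by_year: dict[int, SeasonSeries],
    season_dates: dict[int, list[dt.date]],
    max_width: int,
) -> np.ndarray:
    """Mean-over-years capture for every (width, start) pair.

    Returns C of shape (max_width, n) where C[w-1, s] is the mean capture
    of the window starting at season night s with width w; infeasible
    starts hold NaN.  Seasons are aligned by night offset from the season
    start, so the same (start, width) recurs across years.
    """
    n = min(len(season_dates[y]) for y in series_by_year)
    n_widths = min(max_width, n)
    caps = []
    for y, series in series_by_year.items():
        arr = _season_positions(series, season_dates)[:n]
        total = arr.sum()
        cum = np.concatenate([[0.0], np.cumsum(arr)])
        yearly = np.full((n_widths, n), np.nan)
        for w in range(1, n_widths + 1):
            ns = n - w + 1
            win = cum[w:w + ns] - cum[:ns]
            yearly[w - 1, :ns] = win / total if total > 0 else 0.0
        caps.append(yearly)
    # NaN patterns (infeasible starts) are identical across years, so a
    # plain mean propagates them without all-NaN-slice warnings.
    return np.stack(caps).mean(axis=0)


def optimal_fixed_window(
    series_by_year: dict[int, SeasonSeries],
    season_dates: dict[int, list[dt.date]],
    target_fraction: float,
    max_width: int = MAX_WINDOW_NIGHTS,
) -> FixedWindow:
    """Exhaustive search for the narrowest historical window.

    Iterates over widths 1..max_width and every feasible start; per
    (width, start) the capture is averaged across derivation years, and
    the minimum width whose mean capture reaches the target wins.  Among
    equal widths the start with the highest mean capture is kept, with
    remaining ties going to the earliest start.  If no window reaches the
    target, the best widest window is returned flagged infeasible.

    ``season_dates`` maps each derivation year to its season's calendar
    dates (the evaluation year is deliberately absent from
    ``series_by_year``).
    """
    if not 0 < target_fraction <= 1:
        raise SelectionError("target_fraction must lie in (0, 1]")
    if not series_by_year:
        raise SelectionError("at least one derivation year is required")
    missing = set(series_by_year) - set(season_dates)
    if missing:
        raise SelectionError(f"season dates missing for years {sorted(missing)}")
    mean_caps = _window_captures(series_by_year, season_dates, max_width)
    n = mean_caps.shape[1]
    some_year = next(iter(series_by_year))
    dates = season_dates[some_year]
    for w in range(1, min(max_width, n) + 1):
        row = mean_caps[w - 1, : n - w + 1]
        ok = row >= target_fraction - 1e-12
        if ok.any():
            best = int(np.flatnonzero(row == row[ok].max())[0])
            return FixedWindow(
                start_index=best, width=w, mean_capture=float(row[best]),
                start_month_day=dates[best].strftime("%m-%d"),
            )
    w = min(max_width, n)
    row = mean_caps[w - 1, : n - w + 1]
    best = int(np.nanargmax(row))
    log.warning("no window of width <= %d reaches target %.2f",
                max_width, target_fraction)
    return FixedWindow(
        start_index=best, width=w, mean_capture=float(row[best]),
        start_month_day=dates[best].strftime("%m-%d"), feasible=False,
    )


def evaluate_window(
    window: FixedWindow,
    measured: SeasonSeries,
    season_dates_eval: list[dt.date],
    target_fraction: float | None = None,
) -> SelectionResult:
    """Score a fixed window on the evaluation year.

    ``n_nights`` counts calendar nights in the window, including nights
    with missing data (mitigation would still run on them); capture comes
    from the evaluation year's measured passage only.
    """
    if window.width < 1:
        raise ValidationError("window width must be >= 1")
    n = len(season_dates_eval)
    if window.start_index + window.width > n:
        raise ValidationError("window extends past the season bounds")
    win_dates = season_dates_eval[
        window.start_index: window.start_index + window.width
    ]
    action = {d.isoformat() for d in win_dates}
    nights, traffic = _series_arrays(measured)
    sel = np.isin(nights.astype(str), list(action))
    total = traffic.sum()
    capture = float(traffic[sel].sum() / total) if total > 0 else 0.0
    return SelectionResult(
        method="fixed_window",
        station_id=measured.station_id,
        season=measured.season,
        year=measured.year,
        action_nights=frozenset(action),
        n_nights=int(window.width),
        capture_fraction=capture,
        target_fraction=float(
            target_fraction if target_fraction is not None
            else window.mean_capture
        ),
        detail={"start": win_dates[0].isoformat(), "width": window.width,
                "mean_capture_derivation": window.mean_capture,
                "window_feasible": window.feasible},
    )


def results_table(results: list[SelectionResult]) -> pd.DataFrame:
    """Flatten SelectionResults into the documented results table."""
    import json as _json

    rows = [{
        "method": r.method, "station_id": r.station_id, "season": r.season,
        "year": r.year, "target_fraction": r.target_fraction,
        "n_nights": r.n_nights, "capture_fraction": r.capture_fraction,
        "threshold_or_window": _json.dumps(r.detail, sort_keys=True),
    } for r in results]
    return pd.DataFrame(rows)
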