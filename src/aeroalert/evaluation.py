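"""Summary analytics: passage concentration, method comparisons and
capture-versus-action-night curves.

These utilities quantify how concentrated migratory passage is across a
season's nights (e.g. the share of birds moving on the top 10% of
nights), compare the action-night budgets of the selection strategies
with paired t-tests, and report linear trends of night counts against
station latitude and longitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .traffic import SeasonSeries


@dataclass
class ConcentrationSummary:
    """Share of passage captured by the top f-fraction of nights."""

    station_id: str
    season: str
    year: int
    shares: dict[float, float]


def concentration_curve(
    series: SeasonSeries, fractions=(0.05, 0.10, 0.25, 0.50, 1.0)
) -> ConcentrationSummary:
    """Concentration statistic for one season series.

    For each fraction f, nights are ranked by traffic descending and the
    top ceil(f * N) nights' share of total passage is reported.
    """
    traffic = series.nights["traffic"].to_numpy(dtype=float)
    total = traffic.sum()
    if total <= 0:
        raise ValidationError(
            f"total passage is zero for {series.station_id} {series.year}"
        )
    ranked = np.sort(traffic)[::-1]
    cum = np.cumsum(ranked)
    n = ranked.size
    shares = {}
    for f in fractions:
        if not 0 < f <= 1:
            raise ValidationError(f"fraction {f} outside (0, 1]")
        k = int(np.ceil(f * n))
        shares[float(f)] = float(cum[k - 1] / total)
    return ConcentrationSummary(
        series.station_id, series.season, series.year, shares
    )


def concentration_table(
    series_list: list[SeasonSeries], fractions=(0.05, 0.10, 0.25, 0.50, 1.0)
) -> pd.DataFrame:
    rows = []
    for s in series_list:
        c = concentration_curve(s, fractions)
        for f, share in c.shares.items():
            rows.append({"station_id": c.station_id, "season": c.season,
                         "year": c.year, "fraction": f, "share": share})
    return pd.DataFrame(rows)


def compare_methods(
    results: pd.DataFrame,
    method_a: str,
    method_b: str,
    stations: pd.DataFrame | None = None,
) -> dict:
    """Paired comparison of action-night counts between two methods.

    ``results`` is a results table (one row per method x station x season
    x year x target).  Differences (b - a) are computed on matched
    station-season-year-target keys only, then summarised with mean, SD
    and a two-sided paired t-test.  With zero-variance differences the t
    statistic is undefined and flagged.  If ``stations`` (station_id,
    latitude, longitude) is given, univariate OLS fits of each method's
    n_nights on latitude and on longitude are reported.
    """
    keys = ["station_id", "season", "year", "target_fraction"]
    a = results[results["method"] == method_a][keys + ["n_nights"]]
    b = results[results["method"] == method_b][keys + ["n_nights"]]
    j = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if len(j) < 2:
        raise ValidationError("fewer than 2 matched keys to compare")
    diff = (j["n_nights_b"] - j["n_nights_a"]).to_numpy(dtype=float)
    out = {
        "method_a": method_a,
        "method_b": method_b,
        "n_pairs": int(len(diff)),
        "mean_difference": float(diff.mean()),
        "sd_difference": float(diff.std(ddof=1)),
        "share_b_greater": float((diff > 0).mean()),
    }
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            out.update(t_statistic=0.0, p_value=1.0, degenerate=True)
        else:
            out.update(t_statistic=float("nan"), p_value=float("nan"),
                       degenerate=True)
    else:
        t, p = stats.ttest_rel(j["n_nights_b"], j["n_nights_a"])
        out.update(t_statistic=float(t), p_value=float(p), degenerate=False)
    if stations is not None:
        out["spatial_trends"] = {
            m: spatial_trends(results[results["method"] == m], stations)
            for m in (method_a, method_b)
        }
    return out


def spatial_trends(results: pd.DataFrame, stations: pd.DataFrame) -> dict:
    """Univariate OLS of n_nights on latitude and on longitude.

    Returns slope, standard error, 95% CI and p-value per predictor.
    Requires at least three distinct stations.
    """
    import statsmodels.api as sm

    df = results.merge(stations, on="station_id")
    out = {}
    for pred in ("latitude", "longitude"):
        x = sm.add_constant(df[pred].to_numpy(dtype=float))
        fit = sm.OLS(df["n_nights"].to_numpy(dtype=float), x).fit()
        ci = fit.conf_int()[1]
        out[pred] = {
            "slope": float(fit.params[1]),
            "se": float(fit.bse[1]),
            "ci95": (float(ci[0]), float(ci[1])),
            "p_value": float(fit.pvalues[1]),
        }
    return out


def capture_curve(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate capture-vs-action-nights across stations and years.

    Returns one row per (method, target_fraction) with the mean night
    count and mean realized capture, sorted by method then target.
    """
    grouped = (
        results.groupby(["method", "target_fraction"], as_index=False)
        .agg(mean_n_nights=("n_nights", "mean"),
             mean_capture=("capture_fraction", "mean"),
             n=("n_nights", "size"))
        .sort_values(["method", "target_fraction"], ignore_index=True)
    )
    return grouped
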