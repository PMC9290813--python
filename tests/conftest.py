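"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from aeroalert import SimulationConfig, StationConfig
from aeroalert.traffic import SeasonSeries


def make_series(
    traffic,
    station_id: str = "KTST",
    season: str = "spring",
    year: int = 2015,
    start: dt.date | None = None,
    valid: bool = True,
) -> SeasonSeries:
    """Build a SeasonSeries from a plain list of nightly traffic values,
    assigning consecutive dates from the season start."""
    start = start or dt.date(year, 3, 1)
    nights = pd.DataFrame({
        "night_id": [
            (start + dt.timedelta(days=i)).isoformat()
            for i in range(len(traffic))
        ],
        "traffic": np.asarray(traffic, dtype=float),
    })
    return SeasonSeries(
        station_id=station_id, season=season, year=year, nights=nights,
        total_passage=float(np.sum(traffic)), valid=valid,
    )


@pytest.fixture(scope="session")
def one_station():
    return StationConfig("KTST", 30.0, -97.0, 10.0)


@pytest.fixture(scope="session")
def small_config(one_station):
    """One station, one spring season — the generator's smallest full unit."""
    return SimulationConfig(stations=[one_station], years=[2015], seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(weather, profiles, truth) for the small config, simulated once."""
    from aeroalert import synthetic

    weather = synthetic.simulate_weather(small_config)
    profiles, truth = synthetic.simulate_migration(small_config, weather)
    return weather, profiles, truth
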