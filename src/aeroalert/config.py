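"""Configuration objects for the simulation and pipeline.

A *season* is the fixed calendar span used throughout: spring runs
March 1 – June 10 and autumn August 1 – November 10, each exactly 102
nights.  A *night* is labelled by the local calendar date of sunset; all
samples taken after midnight still carry that night's label.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .errors import ConfigurationError

#: (start month-day, end month-day), inclusive on both ends -> 102 nights.
SEASON_BOUNDS = {
    "spring": ((3, 1), (6, 10)),
    "autumn": ((8, 1), (11, 10)),
}

MAX_SEASON_NIGHTS = 102

#: Height-bin lower edges for activity profiles, m above ground level.
PROFILE_BINS_M = tuple(range(0, 3000, 100))

#: Weather grid heights, m above ground level.
WEATHER_HEIGHTS_M = tuple(range(0, 3001, 100))

#: Weather temporal resolution, hours.
WEATHER_STEP_H = 3

#: Profile temporal resolution, minutes after sunset.
PROFILE_STEP_MIN = 30


@dataclass(frozen=True)
class StationConfig:
    """One radar-like station.

    night_length is the sunset-to-sunrise duration in hours, held fixed
    for a station-season (no solar ephemeris is computed).  It must be a
    multiple of 0.5 h so nights land on the 30-min sampling grid.
    """

    station_id: str
    latitude: float
    longitude: float
    night_length: float = 10.0

    def __post_init__(self) -> None:
        if not self.station_id:
            raise ConfigurationError("station_id must be non-empty")
        if not 24.0 <= self.latitude <= 49.0:
            raise ConfigurationError(
                f"latitude {self.latitude} outside [24, 49] for {self.station_id}"
            )
        if not -125.0 <= self.longitude <= -66.0:
            raise ConfigurationError(
                f"longitude {self.longitude} outside [-125, -66] for {self.station_id}"
            )
        if not 8.0 <= self.night_length <= 14.0:
            raise ConfigurationError(
                f"night_length {self.night_length} outside [8, 14] for {self.station_id}"
            )
        if (self.night_length * 2) % 1 != 0:
            raise ConfigurationError("night_length must be a multiple of 0.5 h")


@dataclass
class SimulationConfig:
    """Full description of one synthetic multi-station, multi-year study.

    The latent nightly intensity of migration at a station is

        I_n = A * exp(-(d_n - mu)^2 / (2 sd^2)) * exp(beta * F_n + sigma * z_n)

    with ``A = envelope_amplitude`` (cm^2/km^2 per night, summed over
    height bins), ``d_n`` the ordinal date, ``mu/sd`` the phenology peak
    and width, ``F_n`` the standardized nightly tailwind favorability and
    ``z_n ~ N(0,1)`` the unpredictable night-to-night pulse.
    """

    stations: Sequence[StationConfig]
    years: Sequence[int]
    season: str = "spring"
    season_start: str | None = None  # "MM-DD"; default from SEASON_BOUNDS
    season_end: str | None = None
    phenology_peak_mu: float | None = None  # ordinal date; default mid-season
    phenology_sd: float = 15.0  # nights
    envelope_amplitude: float = 2.0e5  # cm^2/km^2 per night at the peak
    pulse_beta: float = 0.8  # weather sensitivity, unitless
    pulse_sigma: float = 1.1  # log-scale nightly pulse noise SD
    weather_ar1_rho: float = 0.7  # synoptic persistence, in [0, 1)
    obs_sigma: float = 0.3  # log-scale 30-min observation noise SD
    dropout_rate: float = 0.0  # probability a night is missing
    altitude_scale: float = 1000.0  # m; e-folding height of activity
    forecast_error_sd: float = 0.0  # relative SD of the forecast-weather error
    seed: int = 0

    def __post_init__(self) -> None:
        self.stations = tuple(self.stations)
        self.years = tuple(int(y) for y in self.years)
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if not self.stations:
            raise ConfigurationError("at least one station is required")
        ids = [s.station_id for s in self.stations]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate station_id in {ids}")
        if not self.years:
            raise ConfigurationError("at least one year is required")
        if self.season not in SEASON_BOUNDS:
            raise ConfigurationError(f"season must be one of {sorted(SEASON_BOUNDS)}")
        if not 0.0 <= self.weather_ar1_rho < 1.0:
            raise ConfigurationError("weather_ar1_rho must lie in [0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        for name in ("phenology_sd", "pulse_sigma", "obs_sigma", "forecast_error_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.phenology_sd == 0:
            raise ConfigurationError("phenology_sd must be > 0")
        if self.altitude_scale <= 0:
            raise ConfigurationError("altitude_scale must be > 0")
        if self.envelope_amplitude < 0:
            raise ConfigurationError("envelope_amplitude must be >= 0")
        # Season span check uses an arbitrary (non-leap) year.
        if len(self.season_dates(2001)) > MAX_SEASON_NIGHTS:
            raise ConfigurationError(
                f"season spans more than {MAX_SEASON_NIGHTS} nights"
            )

    # -- derived calendar quantities ----------------------------------

    def _bounds(self) -> tuple[tuple[int, int], tuple[int, int]]:
        start, end = SEASON_BOUNDS[self.season]
        if self.season_start is not None:
            m, d = self.season_start.split("-")
            start = (int(m), int(d))
        if self.season_end is not None:
            m, d = self.season_end.split("-")
            end = (int(m), int(d))
        return start, end

    def season_dates(self, year: int) -> list[dt.date]:
        """Calendar dates of every night of the season in ``year``."""
        (m0, d0), (m1, d1) = self._bounds()
        start = dt.date(year, m0, d0)
        end = dt.date(year, m1, d1)
        if end < start:
            raise ConfigurationError("season_end precedes season_start")
        n = (end - start).days + 1
        return [start + dt.timedelta(days=i) for i in range(n)]

    def peak_ordinal(self, year: int) -> float:
        if self.phenology_peak_mu is not None:
            return float(self.phenology_peak_mu)
        dates = self.season_dates(year)
        mid = dates[len(dates) // 2]
        return float(mid.timetuple().tm_yday)

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stations"] = [asdict(s) for s in self.stations]
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["stations"] = [StationConfig(**s) for s in d["stations"]]
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end run description: simulation, model sizing and targets."""

    simulation: SimulationConfig
    n_rounds: int = 1000
    early_stopping_rounds: int = 50
    max_train_rows: int | None = None
    target_fractions: Sequence[float] = (0.25, 0.5, 0.75)
    exploration_grid: Sequence[float] = field(
        default_factory=lambda: tuple(round(0.05 * i, 2) for i in range(1, 20))
    )
    cross_section_cm2: float = 11.0
    bin_height_km: float = 0.1
    min_valid_nights: int = 100

    def __post_init__(self) -> None:
        self.target_fractions = tuple(float(t) for t in self.target_fractions)
        self.exploration_grid = tuple(float(t) for t in self.exploration_grid)
        for t in self.target_fractions + self.exploration_grid:
            if not 0 < t <= 1:
                raise ConfigurationError(f"target fraction {t} outside (0, 1]")
        if self.n_rounds < 1:
            raise ConfigurationError("n_rounds must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["target_fractions"] = list(self.target_fractions)
        d["exploration_grid"] = list(self.exploration_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)
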