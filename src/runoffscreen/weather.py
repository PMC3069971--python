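"""Synthetic daily weather series with Mediterranean seasonality.

The California crop scenarios assume winter-dominant (November–March) rainfall
with growing-season irrigation. This module generates multi-year daily records
of precipitation, reference evapotranspiration and irrigation with that
structure, so simulations are reproducible without station met files.

Rainfall occurrence follows a two-state (wet/dry) daily process with a
season-specific wet-day probability; wet-day depths are exponential.
Reference ET follows a smooth annual sinusoid peaking in mid-July.
Irrigation is a fixed annual calendar of (month-day, depth) events, as the
scenarios prescribe management rather than simulating it adaptively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeatherConfig",
    "WeatherSeries",
    "generate_weather",
    "read_weather",
    "write_weather",
]

#: CSV column order for weather files.
WEATHER_COLUMNS = ("date", "precip_mm", "et_mm", "irrigation_mm")


class WeatherFormatError(ValueError):
    """Raised for malformed weather files (missing columns, gaps in dates)."""


@dataclass(frozen=True)
class WeatherConfig:
    """Configuration of the synthetic weather generator.

    Parameters
    ----------
    n_years : int
        Number of complete calendar years to generate (>= 1).
    start_year : int
        First calendar year of the series.
    wet_season_months : frozenset of int
        Months (1-12) forming the wet season. Default November–March.
    mean_annual_rain_mm : float
        Target long-run mean annual rainfall. Default 285 mm (Fresno-like).
    wet_day_prob_wet_season, wet_day_prob_dry_season : float
        Daily probability of rain inside / outside the wet season.
    mean_storm_depth_mm : float or None
        Mean of the exponential wet-day depth. If None it is derived so the
        expected annual total equals ``mean_annual_rain_mm``.
    et_annual_mm : float
        Annual reference evapotranspiration, distributed sinusoidally.
    et_seasonal_amplitude : float
        Relative amplitude of the ET sinusoid (0 = flat, <= 1).
    irrigation_schedule : tuple of (str, float)
        Annual irrigation events as ("MM-DD", depth_mm), repeated every year.
    seed : int
        Seed of the pseudo-random generator.
    """

    n_years: int = 30
    start_year: int = 1991
    wet_season_months: frozenset = frozenset({11, 12, 1, 2, 3})
    mean_annual_rain_mm: float = 285.0
    wet_day_prob_wet_season: float = 0.28
    wet_day_prob_dry_season: float = 0.03
    mean_storm_depth_mm: float | None = None
    et_annual_mm: float = 1400.0
    et_seasonal_amplitude: float = 0.85
    irrigation_schedule: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError(f"n_years must be >= 1, got {self.n_years}")
        for p in (self.wet_day_prob_wet_season, self.wet_day_prob_dry_season):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"wet-day probability outside [0, 1]: {p}")
        if self.mean_annual_rain_mm < 0:
            raise ValueError("mean_annual_rain_mm must be >= 0")
        if not 0.0 <= self.et_seasonal_amplitude <= 1.0:
            raise ValueError("et_seasonal_amplitude must be in [0, 1]")
        for _, depth in self.irrigation_schedule:
            if depth < 0:
                raise ValueError("irrigation depths must be >= 0")

    @property
    def expected_wet_days_per_year(self) -> float:
        wet_days = sum(
            _DAYS_IN_MONTH[m] for m in self.wet_season_months
        )
        dry_days = 365.25 - wet_days
        return (
            wet_days * self.wet_day_prob_wet_season
            + dry_days * self.wet_day_prob_dry_season
        )

    @property
    def storm_depth_mm(self) -> float:
        """Mean wet-day depth, derived from the annual target if not set."""
        if self.mean_storm_depth_mm is not None:
            return self.mean_storm_depth_mm
        n_wet = self.expected_wet_days_per_year
        if n_wet <= 0:
            return 0.0
        return self.mean_annual_rain_mm / n_wet


_DAYS_IN_MONTH = {
    1: 31, 2: 28.25, 3: 31, 4: 30, 5: 31, 6: 30,
    7: 31, 8: 31, 9: 30, 10: 31, 11: 30, 12: 31,
}


@dataclass
class WeatherSeries:
    """A contiguous daily record of precipitation, reference ET and irrigation.

    All arrays share the length of ``dates`` and are finite and non-negative;
    depths are mm/day.
    """

    dates: pd.DatetimeIndex
    precip_mm: np.ndarray
    et_mm: np.ndarray
    irrigation_mm: np.ndarray

    def __post_init__(self):
        n = len(self.dates)
        self.precip_mm = np.asarray(self.precip_mm, dtype=float)
        self.et_mm = np.asarray(self.et_mm, dtype=float)
        self.irrigation_mm = np.asarray(self.irrigation_mm, dtype=float)
        for name in ("precip_mm", "et_mm", "irrigation_mm"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} dates")
            if n and (not np.all(np.isfinite(arr)) or arr.min() < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise WeatherFormatError("dates are not contiguous daily")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def water_input_mm(self) -> np.ndarray:
        """Total water reaching the soil surface: rain plus irrigation."""
        return self.precip_mm + self.irrigation_mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "precip_mm": self.precip_mm,
                "et_mm": self.et_mm,
                "irrigation_mm": self.irrigation_mm,
            }
        )

    def annual_rain_totals(self) -> pd.Series:
        """Total precipitation per calendar year (mm)."""
        return pd.Series(self.precip_mm, index=self.dates).groupby(
            self.dates.year
        ).sum()


def generate_weather(config: WeatherConfig) -> WeatherSeries:
    """Generate a synthetic daily weather series.

    Deterministic for a fixed ``config.seed``. Rain days are Bernoulli with
    the seasonal probability; depths are exponential with mean
    ``config.storm_depth_mm``; ET is a deterministic sinusoid; irrigation is
    the fixed annual calendar.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.n_years - 1,
                       month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)

    in_wet_season = np.isin(dates.month, list(config.wet_season_months))
    p_wet = np.where(in_wet_season, config.wet_day_prob_wet_season,
                     config.wet_day_prob_dry_season)
    is_rain_day = rng.random(n) < p_wet
    depths = rng.exponential(scale=max(config.storm_depth_mm, 0.0), size=n)
    precip = np.where(is_rain_day, depths, 0.0)

    # reference ET: annual sinusoid peaking mid-July (day-of-year ~197)
    doy = dates.dayofyear.to_numpy(dtype=float)
    et_mean = config.et_annual_mm / 365.25
    et = et_mean * (1.0 + config.et_seasonal_amplitude
                    * np.cos(2.0 * np.pi * (doy - 197.0) / 365.25))
    et = np.clip(et, 0.0, None)

    irrigation = np.zeros(n)
    if config.irrigation_schedule:
        key = dates.strftime("%m-%d")
        for md, depth in config.irrigation_schedule:
            irrigation[key == md] += depth

    return WeatherSeries(dates=dates, precip_mm=precip, et_mm=et,
                         irrigation_mm=irrigation)


def write_weather(series: WeatherSeries, path) -> None:
    """Write a weather series to CSV (columns: date,precip_mm,et_mm,irrigation_mm)."""
    series.to_frame().to_csv(path, index=False)


def read_weather(path) -> WeatherSeries:
    """Read a weather CSV written by :func:`write_weather`.

    Raises
    ------
    WeatherFormatError
        If required columns are missing or the daily dates have gaps.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"weather file missing columns: {missing}")
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="%Y-%m-%d"))
    return WeatherSeries(
        dates=dates,
        precip_mm=df["precip_mm"].to_numpy(dtype=float),
        et_mm=df["et_mm"].to_numpy(dtype=float),
        irrigation_mm=df["irrigation_mm"].to_numpy(dtype=float),
    )
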