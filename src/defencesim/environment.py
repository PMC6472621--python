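"""Deterministic daily weather drivers and thermal time.

Weather is a fixed pair of seasonal sinusoids (air temperature and incident
photosynthetically active radiation) emulating average conditions in the
Netherlands at ~52 deg N. Real meteorological ingestion is out of scope; a
CSV override (columns: doy, temp, par) is supported for user-supplied series.

Thermal time is accumulated as growing degree days (GDD): daily mean
temperature above a base temperature, clamped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .params import SimParams

__all__ = [
    "WeatherDay",
    "ThermalClock",
    "daily_temperature",
    "daily_par",
    "gdd_increment",
    "weather_series",
    "weather_from_frame",
]

_DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class WeatherDay:
    """One day of environmental drivers."""

    doy: int            # day of year, 1..365
    temp: float         # mean air temperature, deg C
    par: float          # incident PAR, MJ m^-2 d^-1

    def __post_init__(self) -> None:
        if self.par < 0:
            raise ValueError("par must be non-negative")


@dataclass
class ThermalClock:
    """Accumulates growing degree days; increments are never negative."""

    t_base: float = 0.0
    gdd_cum: float = field(default=0.0)

    def advance(self, temp: float) -> float:
        """Advance one day at the given mean temperature; return the increment."""
        inc = gdd_increment(temp, self.t_base)
        self.gdd_cum += inc
        return inc


def _check_doy(doy: int) -> None:
    if not 1 <= doy <= _DAYS_PER_YEAR:
        raise ValueError(f"doy must be in [1, {_DAYS_PER_YEAR}], got {doy}")


def daily_temperature(doy: int, params: SimParams | None = None) -> float:
    """Mean air temperature (deg C) for a day of year.

    A smooth annual sinusoid: mean + amplitude * cos(2*pi*(doy - peak)/365),
    peaking in mid July by default.
    """
    _check_doy(doy)
    p = params or SimParams()
    phase = 2.0 * math.pi * (doy - p.temp_peak_doy) / _DAYS_PER_YEAR
    return p.temp_mean + p.temp_amp * math.cos(phase)


def daily_par(doy: int, params: SimParams | None = None) -> float:
    """Incident PAR (MJ m^-2 d^-1) for a day of year; non-negative sinusoid."""
    _check_doy(doy)
    p = params or SimParams()
    phase = 2.0 * math.pi * (doy - p.par_peak_doy) / _DAYS_PER_YEAR
    return max(0.0, p.par_mean + p.par_amp * math.cos(phase))


def gdd_increment(temp: float, t_base: float = 0.0) -> float:
    """Thermal-time increment for a one-day step: max(0, temp - t_base)."""
    return max(0.0, temp - t_base)


def weather_series(params: SimParams | None = None) -> list[WeatherDay]:
    """The full simulation window (default: 31 March -> 2 August, 124 days)."""
    p = params or SimParams()
    days = []
    for step in range(p.n_days):
        doy = (p.start_doy + step - 1) % _DAYS_PER_YEAR + 1
        days.append(WeatherDay(doy=doy, temp=daily_temperature(doy, p), par=daily_par(doy, p)))
    return days


def weather_from_frame(frame: pd.DataFrame) -> list[WeatherDay]:
    """Build a driver series from a table with columns doy, temp, par.

    Rows are used in order; this is the CSV-override hook for user weather.
    """
    required = {"doy", "temp", "par"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    return [
        WeatherDay(doy=int(row.doy), temp=float(row.temp), par=float(row.par))
        for row in frame.itertuples(index=False)
    ]
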