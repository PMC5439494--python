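"""Daily meteorological forcing: weather I/O, reference evapotranspiration, thermal time.

Reference evapotranspiration (ET0) follows the FAO-56 daily Penman-Monteith
formulation for a well-watered grass reference surface: saturation and actual
vapour pressure from the Tmin/Tmax and RHmin/RHmax extremes, net radiation from
measured shortwave radiation against a clear-sky envelope, and soil heat flux
G = 0 at the daily time step.

Thermal time is accumulated as growing degree days (GDD): the Tmin/Tmax mean,
clamped into the [Tb, Tu] development range, minus the base temperature Tb.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WeatherDay",
    "SiteConfig",
    "ThermalTime",
    "SeasonWindow",
    "SchemaError",
    "SequencingError",
    "load_weather",
    "compute_et0",
    "et0_series",
    "compute_gdd",
    "gdd_series",
    "season_calendar",
]

#: canonical weather column names and their meaning/units
WEATHER_COLUMNS = {
    "date": "calendar date (ISO-8601)",
    "tmin": "daily minimum air temperature (degC)",
    "tmax": "daily maximum air temperature (degC)",
    "rhmin": "daily minimum relative humidity (%)",
    "rhmax": "daily maximum relative humidity (%)",
    "rs": "daily shortwave radiation (MJ m-2 day-1)",
    "u2": "mean wind speed at 2 m (m s-1)",
    "pr": "daily precipitation (mm)",
}


class SchemaError(ValueError):
    """A mandatory weather column is missing or unmapped."""


class SequencingError(ValueError):
    """Weather dates are not a strictly increasing daily sequence."""


@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological forcing."""

    date: _dt.date
    tmin: float  # degC
    tmax: float  # degC
    rhmin: float  # %
    rhmax: float  # %
    rs: float  # MJ m-2 day-1
    u2: float  # m s-1
    pr: float  # mm

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise ValueError(f"tmin {self.tmin} > tmax {self.tmax} on {self.date}")
        if not (0.0 <= self.rhmin <= self.rhmax <= 100.0):
            raise ValueError(f"require 0 <= rhmin <= rhmax <= 100 on {self.date}")
        if self.rs < 0 or self.u2 < 0 or self.pr < 0:
            raise ValueError(f"rs, u2, pr must be non-negative on {self.date}")


@dataclass(frozen=True)
class SiteConfig:
    """Static site description used by the ET0 computation."""

    latitude: float  # decimal degrees, positive north
    elevation: float = 0.0  # m above sea level
    anemometer_height: float = 2.0  # m

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValueError("latitude must lie within [-90, 90] degrees")
        if self.anemometer_height <= 0:
            raise ValueError("anemometer height must be positive")


@dataclass
class ThermalTime:
    """Thermal-time accumulator for crop development.

    tb/tu bound the development-effective temperature range; the cumulative
    total is in degC day since the season start.
    """

    tb: float = 0.0
    tu: float = 25.0
    cumulative: float = 0.0

    def __post_init__(self) -> None:
        if self.tb >= self.tu:
            raise ValueError("base temperature must be below upper temperature")

    def add_day(self, tmin: float, tmax: float) -> float:
        """Accumulate one day; returns the daily GDD increment."""
        g = compute_gdd(tmin, tmax, self.tb, self.tu)
        self.cumulative += g
        return g


# ---------------------------------------------------------------------------
# weather input


def load_weather(
    path: str | Path,
    schema: dict[str, str] | None = None,
    sep: str | None = None,
    interpolate_gaps: bool = False,
) -> pd.DataFrame:
    """Read and validate a daily weather table.

    Parameters
    ----------
    path
        Delimited text file with one row per day and an ISO-8601 date column.
    schema
        Optional mapping from canonical names (``tmin`` ...) to the file's
        column names; identity by default.
    sep
        Field delimiter; sniffed when None.
    interpolate_gaps
        If True, missing *values* spanning at most 2 consecutive days are
        filled linearly; longer runs (or any missing value when False) raise.
        Missing *dates* always raise: silent infill would corrupt the water
        balance.

    Returns
    -------
    DataFrame with the canonical columns, indexed 0..n-1, ``date`` as
    ``datetime.date``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep, engine="python")
    mapping = {k: k for k in WEATHER_COLUMNS}
    if schema:
        mapping.update(schema)
    missing = [k for k, col in mapping.items() if col not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory weather column(s): {', '.join(sorted(missing))}")
    df = raw[[mapping[k] for k in WEATHER_COLUMNS]].copy()
    df.columns = list(WEATHER_COLUMNS)
    df["date"] = pd.to_datetime(df["date"]).dt.date

    dates = pd.to_datetime(df["date"])
    deltas = dates.diff().dropna()
    if (deltas <= pd.Timedelta(0)).any():
        bad = dates[1:][deltas.to_numpy() <= pd.Timedelta(0)].iloc[0]
        raise SequencingError(f"dates not strictly increasing at {bad.date()}")
    gaps = deltas[deltas > pd.Timedelta(days=1)]
    if len(gaps):
        i = gaps.index[0]
        raise SequencingError(
            f"non-daily step: gap between {dates[i - 1].date()} and {dates[i].date()}"
        )

    value_cols = [c for c in WEATHER_COLUMNS if c != "date"]
    if df[value_cols].isna().any().any():
        if not interpolate_gaps:
            n = int(df[value_cols].isna().sum().sum())
            raise ValueError(f"{n} missing weather value(s); pass interpolate_gaps=True "
                             "to fill runs of <= 2 days")
        for c in value_cols:
            runs = _nan_run_lengths(df[c].to_numpy(dtype=float))
            if runs and max(runs) > 2:
                raise ValueError(f"missing-value run longer than 2 days in column '{c}'")
        df[value_cols] = df[value_cols].interpolate(limit_area="inside")
        if df[value_cols].isna().any().any():
            raise ValueError("missing values at the series boundary cannot be interpolated")

    # row-wise physical invariants
    bad = (df["tmin"] > df["tmax"]) | (df["rhmin"] > df["rhmax"]) \
        | (df["rhmin"] < 0) | (df["rhmax"] > 100) \
        | (df[["rs", "u2", "pr"]] < 0).any(axis=1)
    if bad.any():
        raise ValueError(f"invalid weather values on {df.loc[bad, 'date'].iloc[0]}")
    return df.reset_index(drop=True)


def _nan_run_lengths(x: np.ndarray) -> list[int]:
    runs, n = [], 0
    for v in x:
        if np.isnan(v):
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


# ---------------------------------------------------------------------------
# FAO-56 daily Penman-Monteith reference evapotranspiration

_GSC = 0.0820  # solar constant, MJ m-2 min-1
_SIGMA = 4.903e-9  # Stefan-Boltzmann, MJ K-4 m-2 day-1
_ALBEDO = 0.23  # grass reference surface


def _svp(t: np.ndarray | float) -> np.ndarray | float:
    """Saturation vapour pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def extraterrestrial_radiation(latitude: float, doy: np.ndarray | int):
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1)."""
    phi = math.radians(latitude)
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-math.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / math.pi) * _GSC * dr * (
        ws * math.sin(phi) * np.sin(delta)
        + math.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def et0_fao56(
    tmin,
    tmax,
    rhmin,
    rhmax,
    rs,
    u2,
    latitude: float,
    elevation: float,
    doy,
):
    """Vectorised FAO-56 daily reference evapotranspiration (mm day-1).

    Soil heat flux is taken as zero at the daily step; the result is clipped
    at zero (the radiation term can otherwise push slightly negative in
    winter).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmean = (tmin + tmax) / 2.0

    delta = 4098.0 * _svp(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    es = (_svp(tmin) + _svp(tmax)) / 2.0
    ea = (_svp(tmin) * np.asarray(rhmax, float) / 100.0
          + _svp(tmax) * np.asarray(rhmin, float) / 100.0) / 2.0
    ea = np.minimum(ea, es)

    ra = extraterrestrial_radiation(latitude, doy)
    rso = (0.75 + 2e-5 * elevation) * ra
    rs = np.asarray(rs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0, np.clip(rs / np.where(rso > 0, rso, 1.0), 0.0, 1.0), 1.0)
    rns = (1.0 - _ALBEDO) * rs
    tkmin, tkmax = tmin + 273.16, tmax + 273.16
    rnl = (_SIGMA * (tkmin ** 4 + tkmax ** 4) / 2.0
           * (0.34 - 0.14 * np.sqrt(ea))
           * np.clip(1.35 * rel - 0.35, 0.0, None))
    rn = rns - rnl

    u2 = np.asarray(u2, dtype=float)
    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return np.maximum(num / den, 0.0)


def compute_et0(day: WeatherDay, site: SiteConfig, doy: int | None = None) -> float:
    """Daily reference evapotranspiration for one day (mm day-1)."""
    if doy is None:
        doy = day.date.timetuple().tm_yday
    if not 1 <= doy <= 366:
        raise ValueError("day of year must lie in [1, 366]")
    return float(
        et0_fao56(day.tmin, day.tmax, day.rhmin, day.rhmax, day.rs, day.u2,
                  site.latitude, site.elevation, doy)
    )


def et0_series(weather: pd.DataFrame, site: SiteConfig) -> pd.Series:
    """ET0 for a whole weather table (mm day-1), aligned on its index."""
    doy = pd.to_datetime(weather["date"]).dt.dayofyear.to_numpy()
    vals = et0_fao56(
        weather["tmin"].to_numpy(), weather["tmax"].to_numpy(),
        weather["rhmin"].to_numpy(), weather["rhmax"].to_numpy(),
        weather["rs"].to_numpy(), weather["u2"].to_numpy(),
        site.latitude, site.elevation, doy,
    )
    return pd.Series(vals, index=weather.index, name="et0")


# ---------------------------------------------------------------------------
# thermal time


def compute_gdd(tmin: float, tmax: float, tb: float = 0.0, tu: float = 25.0) -> float:
    """Daily growing degree days: clamp(mean(tmin, tmax), tb, tu) - tb."""
    if tmin > tmax:
        raise ValueError("tmin must not exceed tmax")
    tmean = (tmin + tmax) / 2.0
    return max(min(tmean, tu), tb) - tb


def gdd_series(weather: pd.DataFrame, tb: float = 0.0, tu: float = 25.0) -> pd.Series:
    tmean = (weather["tmin"].to_numpy() + weather["tmax"].to_numpy()) / 2.0
    return pd.Series(np.clip(tmean, tb, tu) - tb, index=weather.index, name="gdd")


# ---------------------------------------------------------------------------
# season calendar


@dataclass
class SeasonWindow:
    """One rotation year mapped onto the calendar.

    Holds the daily cumulative-GDD axis from emergence and the phenology
    milestones (emergence, maximum rooting, senescence onset, maturity)
    expressed both in GDD and as calendar dates.
    """

    label: str
    emergence: _dt.date
    dates: list[_dt.date]
    cum_gdd: np.ndarray  # same length as dates; GDD accumulated from emergence
    milestones_gdd: dict[str, float]
    milestones_date: dict[str, _dt.date | None]

    @property
    def end(self) -> _dt.date:
        return self.dates[-1]

    def date_to_gdd(self, date: _dt.date) -> float:
        """Cumulative GDD (from emergence) on a simulation-grid date."""
        i = (date - self.emergence).days
        if not 0 <= i < len(self.dates):
            raise ValueError(f"{date} outside season window {self.label}")
        return float(self.cum_gdd[i])

    def gdd_to_date(self, gdd: float) -> _dt.date:
        """First date on which the cumulative GDD reaches ``gdd``."""
        i = int(np.searchsorted(self.cum_gdd, gdd, side="left"))
        if i >= len(self.dates):
            raise ValueError(f"{gdd} GDD never reached in season {self.label}")
        return self.dates[i]


def season_calendar(schedule, weather: pd.DataFrame) -> list[SeasonWindow]:
    """Map each rotation year's GDD-denominated phenology onto calendar dates.

    Each season window runs from the year's emergence date to 31 December of
    that calendar year (or the end of the weather series if earlier).  A
    milestone whose thermal-time requirement is not met within the window
    triggers a truncation warning and maps to ``None``.
    """
    dates = pd.to_datetime(weather["date"]).dt.date
    first, last = dates.iloc[0], dates.iloc[-1]
    windows: list[SeasonWindow] = []
    for year in schedule.years:
        p = year.params
        if not (p.eme <= p.root <= p.sen <= p.mat):
            raise ValueError(
                f"{year.label}: phenology milestones must satisfy Eme <= Root <= Sen <= Mat"
            )
        if not (first <= year.emergence <= last):
            raise ValueError(f"{year.label}: emergence {year.emergence} outside weather span")
        end = min(last, _dt.date(year.emergence.year, 12, 31))
        mask = (dates >= year.emergence) & (dates <= end)
        sub = weather.loc[mask.to_numpy()]
        daily = gdd_series(sub, p.tb, p.tu).to_numpy()
        cum = np.cumsum(daily)
        win_dates = list(dates[mask.to_numpy()])
        milestones_gdd = {"eme": p.eme, "root": p.root, "sen": p.sen, "mat": p.mat}
        milestones_date: dict[str, _dt.date | None] = {}
        for name, g in milestones_gdd.items():
            i = int(np.searchsorted(cum, g, side="left"))
            if i >= len(win_dates):
                warnings.warn(
                    f"{year.label}: milestone '{name}' ({g} GDD) exceeds the "
                    f"{cum[-1]:.0f} GDD available; season truncated",
                    stacklevel=2,
                )
                milestones_date[name] = None
            else:
                milestones_date[name] = win_dates[i]
        windows.append(
            SeasonWindow(
                label=year.label,
                emergence=year.emergence,
                dates=win_dates,
                cum_gdd=cum,
                milestones_gdd=milestones_gdd,
                milestones_date=milestones_date,
            )
        )
    return windows
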