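"""Environmental covariates: photoperiod, astronomical seasons, temperature.

Day length follows the CBM model (Forsythe et al. 1995, Ecological
Modelling 80:87-95): solar declination from day-of-year, daylength from
latitude and declination, with the daylength coefficient p = 0.8333
degrees (sunrise/sunset when the solar zenith angle is 90 deg 50', i.e.
including solar disc radius and atmospheric refraction).  This matches
the convention of the standard photoperiod functions used in movement
ecology.

Astronomical seasons are delimited by a small built-in table of
solstice/equinox dates (2018-2021, Northern hemisphere) covering the
study window; each season starts on its boundary date (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from .errors import SeasonRangeError, UnsupportedLatitudeError

__all__ = [
    "SiteSpec",
    "SeasonTable",
    "DEFAULT_SEASON_TABLE",
    "SEASONS",
    "day_length",
    "assign_season",
    "hourly_temperature",
    "celsius_to_fahrenheit",
]

#: Season labels in within-year order (March equinox first).
SEASONS = ("winter", "spring", "summer", "fall")

#: Maximum latitude handled (no polar day/night logic).
_MAX_LAT = 66.5

#: CBM daylength coefficient, degrees (solar zenith 90 deg 50').
CBM_P_DEGREES = 0.8333


@dataclass(frozen=True)
class SiteSpec:
    """Study-site geometry: latitude and the fixed local UTC offset."""

    latitude: float = 38.89292
    utc_offset: float = -5.0

    def __post_init__(self) -> None:
        if abs(self.latitude) > _MAX_LAT:
            raise UnsupportedLatitudeError(
                f"latitude={self.latitude} outside supported band +/-{_MAX_LAT}"
            )


@dataclass(frozen=True)
class SeasonTable:
    """Solstice/equinox dates per year (March, June, September, December)."""

    boundaries: dict = field(default_factory=dict)

    def years(self) -> tuple:
        return tuple(sorted(self.boundaries))


# Northern-hemisphere solstice/equinox calendar dates (local, EST).
DEFAULT_SEASON_TABLE = SeasonTable(
    boundaries={
        2018: (_date(2018, 3, 20), _date(2018, 6, 21), _date(2018, 9, 22), _date(2018, 12, 21)),
        2019: (_date(2019, 3, 20), _date(2019, 6, 21), _date(2019, 9, 23), _date(2019, 12, 21)),
        2020: (_date(2020, 3, 19), _date(2020, 6, 20), _date(2020, 9, 22), _date(2020, 12, 21)),
        2021: (_date(2021, 3, 20), _date(2021, 6, 20), _date(2021, 9, 22), _date(2021, 12, 21)),
    }
)


def day_length(latitude, dates):
    """Photoperiod in hours for ``latitude`` on ``dates`` (CBM model).

    Parameters
    ----------
    latitude : float
        Decimal degrees, |latitude| <= 66.5.
    dates : date-like or sequence of date-like
        Calendar date(s); only day-of-year is used.

    Returns
    -------
    float or ndarray of float
        Hours between dawn and dusk.
    """
    if abs(latitude) > _MAX_LAT:
        raise UnsupportedLatitudeError(
            f"latitude={latitude} outside supported band +/-{_MAX_LAT}"
        )
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]")))
    doy = idx.dayofyear.to_numpy(dtype=float)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.0086 * (doy - 186.0)))
    decl = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    lat = np.deg2rad(latitude)
    p = np.deg2rad(CBM_P_DEGREES)
    a = (np.sin(p) + np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
    a = np.clip(a, -1.0, 1.0)
    dl = 24.0 - (24.0 / np.pi) * np.arccos(a)
    return float(dl[0]) if np.isscalar(dates) or np.ndim(dates) == 0 else dl


def assign_season(dates, table: SeasonTable = DEFAULT_SEASON_TABLE):
    """Astronomical season for each date.

    The season is the one whose boundary (solstice/equinox) is the most
    recent on or before the date; dates before the March equinox belong
    to the winter that started the previous December.
    """
    scalar = np.isscalar(dates) or isinstance(dates, (_date, pd.Timestamp))
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]")))
    years = idx.year.to_numpy()
    known = table.years()
    bad = (years < min(known)) | (years > max(known))
    if bad.any():
        raise SeasonRangeError(
            f"date {idx[bad][0].date()} outside season table years {known[0]}-{known[-1]}"
        )
    out = np.empty(len(idx), dtype=object)
    dts = idx.normalize()
    for yr in np.unique(years):
        b = [pd.Timestamp(d) for d in table.boundaries[int(yr)]]
        sel = years == yr
        d = dts[sel]
        season = np.full(sel.sum(), "winter", dtype=object)
        season[(d >= b[0]) & (d < b[1])] = "spring"
        season[(d >= b[1]) & (d < b[2])] = "summer"
        season[(d >= b[2]) & (d < b[3])] = "fall"
        out[sel] = season
    return out[0] if scalar else out


def celsius_to_fahrenheit(temp_c):
    """Affine Celsius -> Fahrenheit conversion."""
    return np.asarray(temp_c, dtype=float) * 9.0 / 5.0 + 32.0


def hourly_temperature(records: pd.DataFrame) -> pd.DataFrame:
    """Average 30-min temperature records to hourly values, in Fahrenheit.

    Parameters
    ----------
    records : DataFrame with columns ``timestamp`` (datetime-like) and
        ``temp_c``.

    Returns
    -------
    DataFrame with columns ``hour_start``, ``temp_f``, ``n_obs``,
    ``partial`` (True when fewer than 2 half-hour values fell in the
    hour).  Hours with no record at all are simply absent (gaps
    propagate as missing downstream).
    """
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    hour = df["timestamp"].dt.floor("h")
    g = df.groupby(hour)["temp_c"]
    out = g.mean().to_frame("temp_c")
    out["n_obs"] = g.size()
    out["temp_f"] = celsius_to_fahrenheit(out["temp_c"].to_numpy())
    out["partial"] = out["n_obs"] < 2
    out = out.reset_index().rename(columns={"timestamp": "hour_start"})
    return out[["hour_start", "temp_f", "n_obs", "partial"]]
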