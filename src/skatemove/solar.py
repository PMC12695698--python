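"""Sunrise/sunset computation and day/night classification.

Implements the NOAA solar-position equations (Meeus-derived, as used by the
NOAA Solar Calculator) to obtain per-date sunrise and sunset instants in UTC
for a fixed latitude/longitude, typically the centroid of a receiver array.
Accuracy at mid-latitudes is well under one minute, which is ample for
splitting 80-second movement steps into day-time and night-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

# Zenith for official sunrise/sunset: 90° plus refraction and solar radius.
_SUNRISE_ZENITH_DEG = 90.833


def _julian_day(d: date) -> float:
    """Julian day number at 00:00 UT for a calendar date."""
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + day + b - 1524.5


def _solar_geometry(jc: float) -> tuple[float, float]:
    """Return (declination in radians, equation of time in minutes)."""
    l0 = np.deg2rad((280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0)
    m = np.deg2rad(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_center = (
        np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m) * 0.000289
    )
    true_long = np.rad2deg(l0) + eq_center
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = np.deg2rad(mean_obliq) + np.deg2rad(0.00256) * np.cos(omega)
    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))
    y = np.tan(obliq / 2.0) ** 2
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * l0)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * y * y * np.sin(4 * l0)
        - 1.25 * ecc * ecc * np.sin(2 * m)
    )
    return float(decl), float(eot)


def sun_events(d: date, latitude: float, longitude: float) -> tuple[datetime, datetime]:
    """Sunrise and sunset (UTC) for one date at a given location.

    Parameters
    ----------
    d : date of interest (civil date at the site; for western Europe the UTC
        date is the same for all events of interest here).
    latitude, longitude : degrees; longitude positive east.

    Raises
    ------
    ValueError if the sun does not rise or set on that date (polar day/night);
    the intended study latitudes are temperate.
    """
    jd = _julian_day(d)
    jc = (jd + 0.5 - 2451545.0) / 36525.0  # geometry at 12:00 UT
    decl, eot = _solar_geometry(jc)
    phi = np.deg2rad(latitude)
    cos_ha = (
        np.cos(np.deg2rad(_SUNRISE_ZENITH_DEG)) / (np.cos(phi) * np.cos(decl))
        - np.tan(phi) * np.tan(decl)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(f"sun does not rise/set on {d} at latitude {latitude}")
    ha_deg = np.rad2deg(np.arccos(cos_ha))
    noon_min = 720.0 - 4.0 * longitude - eot
    rise_min = noon_min - 4.0 * ha_deg
    set_min = noon_min + 4.0 * ha_deg
    midnight = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    return (midnight + timedelta(minutes=rise_min), midnight + timedelta(minutes=set_min))


def solar_noon(d: date, longitude: float) -> datetime:
    jd = _julian_day(d)
    jc = (jd + 0.5 - 2451545.0) / 36525.0
    _, eot = _solar_geometry(jc)
    midnight = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    return midnight + timedelta(minutes=720.0 - 4.0 * longitude - eot)


@dataclass
class DielCalendar:
    """Per-date sunrise/sunset lookup used to label instants day or night.

    Events are computed lazily from the NOAA routine at (latitude, longitude),
    or can be supplied directly as a table (date, sunrise, sunset) to
    reproduce an external almanac exactly.
    """

    latitude: float
    longitude: float
    events: dict = field(default_factory=dict)
    autofill: bool = True

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DielCalendar":
        """Build from a DataFrame with columns date, sunrise, sunset (ISO-8601)."""
        cal = cls(latitude=np.nan, longitude=np.nan, autofill=False)
        for _, row in table.iterrows():
            d = pd.Timestamp(row["date"]).date()
            rise = pd.Timestamp(row["sunrise"]).tz_convert("UTC").to_pydatetime()
            sset = pd.Timestamp(row["sunset"]).tz_convert("UTC").to_pydatetime()
            cal.events[d] = (rise, sset)
        return cal

    def events_for(self, d: date) -> tuple[datetime, datetime]:
        if d not in self.events:
            if not self.autofill:
                raise KeyError(f"date {d} outside supplied diel calendar")
            self.events[d] = sun_events(d, self.latitude, self.longitude)
        rise, sset = self.events[d]
        if not rise < sset:
            raise ValueError(f"sunrise not before sunset on {d}")
        return rise, sset

    def label(self, instant: datetime | pd.Timestamp) -> str:
        """'day' iff sunrise <= instant < sunset on the instant's UTC date."""
        ts = pd.Timestamp(instant)
        ts = ts.tz_localize("UTC") if ts.tzinfo is None else ts.tz_convert("UTC")
        rise, sset = self.events_for(ts.date())
        return "day" if rise <= ts.to_pydatetime() < sset else "night"

    def label_series(self, instants: pd.Series) -> pd.Series:
        ts = pd.to_datetime(instants, utc=True)
        dates = ts.dt.date
        out = np.empty(len(ts), dtype=object)
        for d in pd.unique(dates):
            rise, sset = self.events_for(d)
            mask = (dates == d).to_numpy()
            sub = ts[mask]
            out[mask] = np.where(
                (sub >= pd.Timestamp(rise)) & (sub < pd.Timestamp(sset)), "day", "night"
            )
        return pd.Series(out, index=instants.index, name="diel")
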