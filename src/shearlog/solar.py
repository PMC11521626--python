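"""Closed-form solar geometry shared by the simulator, geolocation and behaviour stages.

Implements the NOAA low-precision solar position algorithm: fractional-year
harmonic expansions for solar declination and the equation of time, from
which solar elevation, sunrise/sunset at an arbitrary sun elevation angle,
and day length follow.  Accuracy is ~0.01 deg in declination, which is the
error floor quoted for the geolocation round trip.

All angles are degrees, all times UTC.  This is the single solar model in
the package: the light simulator, twilight-based geolocation and the
night/day splitting of immersion data must all import from here so that
their notions of sunrise agree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "fractional_year",
    "solar_declination",
    "equation_of_time",
    "solar_elevation",
    "day_length",
    "sunrise_sunset",
    "solar_noon_utc",
    "latitude_from_day_length",
    "longitude_from_midday",
    "days_from_equinox",
]


def _doy_hour(times: pd.DatetimeIndex | pd.Timestamp):
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]")))
    doy = t.dayofyear.to_numpy(dtype=float)
    hour = (
        t.hour.to_numpy(dtype=float)
        + t.minute.to_numpy(dtype=float) / 60.0
        + t.second.to_numpy(dtype=float) / 3600.0
        + t.microsecond.to_numpy(dtype=float) / 3.6e9
    )
    return doy, hour


def fractional_year(doy, hour=12.0):
    """Fractional year gamma in radians from day of year and UTC hour."""
    return 2.0 * np.pi / 365.0 * (np.asarray(doy, dtype=float) - 1.0 + (np.asarray(hour, dtype=float) - 12.0) / 24.0)


def solar_declination(gamma):
    """Solar declination (degrees) from fractional year (radians)."""
    g = np.asarray(gamma, dtype=float)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return np.degrees(decl)


def equation_of_time(gamma):
    """Equation of time (minutes; apparent minus mean solar time)."""
    g = np.asarray(gamma, dtype=float)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def declination_on(date) -> float:
    """Noon declination (degrees) for a calendar date."""
    doy = pd.Timestamp(date).dayofyear
    return float(solar_declination(fractional_year(doy)))


def solar_elevation(times, latitude, longitude):
    """Solar elevation angle (degrees) at UTC ``times``.

    ``times`` may be a scalar or array-like of timestamps; ``latitude`` and
    ``longitude`` are scalars or arrays broadcastable against ``times``
    (a moving platform passes one position per sample).  Returns an array
    (scalar input -> length-1 array).
    """
    doy, hour = _doy_hour(times)
    gamma = fractional_year(doy, hour)
    decl = np.radians(solar_declination(gamma))
    eqt = equation_of_time(gamma)
    # true solar time in minutes; 4 min per degree of longitude (east positive)
    tst = hour * 60.0 + eqt + 4.0 * np.asarray(longitude, dtype=float)
    ha = np.radians(tst / 4.0 - 180.0)
    lat = np.radians(np.asarray(latitude, dtype=float))
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def _cos_hour_angle(latitude, declination, angle):
    lat = np.radians(latitude)
    decl = np.radians(declination)
    a = np.radians(angle)
    denom = np.cos(lat) * np.cos(decl)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (np.sin(a) - np.sin(lat) * np.sin(decl)) / denom


def day_length(latitude, declination, angle: float = 0.0):
    """Hours between the sun crossing ``angle`` on the way up and down.

    Returns NaN where the sun never reaches (24 h) or never rises above
    (0 -> returns 0.0/24.0 via clipping is *not* done; out-of-range cosines
    yield 0 or 24 explicitly).
    """
    cos_h = _cos_hour_angle(latitude, declination, angle)
    cos_h = np.asarray(cos_h, dtype=float)
    out = np.empty_like(cos_h)
    below = cos_h > 1.0  # sun never reaches the angle: permanent dark
    above = cos_h < -1.0  # sun never sinks to the angle: permanent light
    ok = ~(below | above)
    out[below] = 0.0
    out[above] = 24.0
    out[ok] = 2.0 * np.degrees(np.arccos(cos_h[ok])) / 15.0
    if out.ndim == 0:
        return float(out)
    return out


def solar_noon_utc(date, longitude: float) -> pd.Timestamp:
    """UTC timestamp of local apparent (solar) noon."""
    doy = pd.Timestamp(date).dayofyear
    eqt = float(equation_of_time(fractional_year(doy)))
    minutes = 720.0 - 4.0 * longitude - eqt
    return pd.Timestamp(date).normalize() + pd.Timedelta(minutes=minutes)


def sunrise_sunset(date, latitude: float, longitude: float, angle: float = 0.0):
    """(sunrise, sunset) UTC for the sun crossing ``angle``; (None, None) if no crossing."""
    decl = declination_on(date)
    cos_h = float(_cos_hour_angle(latitude, decl, angle))
    if not -1.0 <= cos_h <= 1.0:
        return None, None
    h_deg = np.degrees(np.arccos(cos_h))
    doy = pd.Timestamp(date).dayofyear
    eqt = float(equation_of_time(fractional_year(doy)))
    base = pd.Timestamp(date).normalize()
    sunrise = base + pd.Timedelta(minutes=720.0 - 4.0 * (longitude + h_deg) - eqt)
    sunset = base + pd.Timedelta(minutes=720.0 - 4.0 * (longitude - h_deg) - eqt)
    return sunrise, sunset


def latitude_from_day_length(day_length_h: float, declination: float, angle: float,
                             tol: float = 1e-4):
    """Invert the sunrise equation: latitude whose day length matches.

    Solves cos H = (sin a - sin phi sin delta)/(cos phi cos delta) for phi,
    with H the half day-length hour angle.  Returns NaN when no root exists
    in (-90, 90) or the equation is degenerate (declination ~ 0: day length
    is latitude-independent at the equinox).
    """
    if not 0.0 < day_length_h < 24.0:
        return float("nan")
    target = np.cos(np.radians(day_length_h * 15.0 / 2.0))

    def f(phi):
        return float(_cos_hour_angle(phi, declination, angle)) - target

    # bracket by scan; the cos(lat) denominator can create spurious
    # crossings near the poles, so verify each root against the day length
    # it implies and keep the best
    grid = np.linspace(-89.5, 89.5, 360)
    vals = _cos_hour_angle(grid, declination, angle) - target
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        return float("nan")
    roots = []
    for i in idx:
        root = brentq(f, grid[i], grid[i + 1], xtol=tol)
        # a threshold crossing implies a real day/night cycle: discard
        # roots where the sun never clears (or never drops to) the horizon
        if not 0.0 < day_length(root, declination, 0.0) < 24.0:
            continue
        if abs(day_length(root, declination, angle) - day_length_h) <= 0.02:
            roots.append(root)
    if not roots:
        return float("nan")
    if max(roots) - min(roots) > 2.0:
        # near an equinox with the twilight angle close to -declination the
        # day length is (almost) the same at well-separated latitudes; the
        # observation cannot tell them apart, so refuse rather than guess
        return float("nan")
    phi = roots[0]
    # degenerate when day length barely depends on latitude (equinox):
    # reject if it moves < 0.002 h (~7 s) across one degree around the root
    t_hi = day_length(min(phi + 0.5, 89.9), declination, angle)
    t_lo = day_length(max(phi - 0.5, -89.9), declination, angle)
    if abs(t_hi - t_lo) < 2e-3:
        return float("nan")
    return float(phi)


def longitude_from_midday(midday_utc, date) -> float:
    """Longitude (degrees east, wrapped to (-180, 180]) from observed solar midday."""
    doy = pd.Timestamp(date).dayofyear
    eqt = float(equation_of_time(fractional_year(doy)))
    midday = pd.Timestamp(midday_utc)
    minutes = (midday - midday.normalize()) / pd.Timedelta(minutes=1)
    lon = (720.0 - eqt - minutes) / 4.0
    return wrap_longitude(lon)


def wrap_longitude(lon):
    """Wrap degrees east into (-180, 180]."""
    wrapped = np.asarray(-((-np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0))
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def days_from_equinox(date) -> float:
    """Days to the nearest zero crossing of solar declination."""
    d = pd.Timestamp(date)
    days = pd.date_range(d - pd.Timedelta(days=200), d + pd.Timedelta(days=200), freq="D")
    decl = solar_declination(fractional_year(days.dayofyear.to_numpy(dtype=float)))
    crossings = np.where(np.diff(np.sign(decl)) != 0)[0]
    if len(crossings) == 0:
        return float("inf")
    cross_dates = days[crossings]
    return float(np.min(np.abs((cross_dates - d) / pd.Timedelta(days=1))))
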