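"""Threshold light-level geolocation.

Twilight events are the times a light trace crosses a fixed intensity
threshold (default 10 logger units, the classic 10 lux rule).  Day length
between a sunrise/sunset pair gives latitude through the sunrise equation
at a calibrated sun elevation angle; the midpoint of the pair gives
longitude through its offset from Greenwich apparent noon.  The sun
elevation angle is calibrated per track against the known colony latitude
during the breeding summer.  Raw daily estimates are smoothed with a
centred 3-day rolling mean and filtered per month with Tukey fences before
monthly means are taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar

DEFAULT_THRESHOLD = 10.0
DEFAULT_ANGLE_CANDIDATES = (-3.0, -3.5, -4.0, -4.5, -5.0)


@dataclass
class PositionEstimate:
    date: pd.Timestamp
    latitude: float
    longitude: float
    day_length: float
    valid: bool
    reason: str = ""


def detect_twilights(trace: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                     refractory_hours: float = 4.0) -> pd.DataFrame:
    """Twilight events: linear-interpolated threshold crossings of the trace.

    Parameters
    ----------
    trace : DataFrame with columns ``timestamp`` (UTC, strictly increasing)
        and ``light`` (>= 0).
    threshold : light level defining twilight (> 0).
    refractory_hours : dark or light spells shorter than this window
        (shading-induced double crossings, nocturnal noise) are removed,
        shortest first.

    Returns a DataFrame with columns ``time``, ``kind`` ('sunrise' when the
    trace rises through the threshold, 'sunset' when it falls) and
    ``flagged`` (merged-duplicate indicator).
    """
    if len(trace) == 0:
        raise ValueError("empty light trace")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = pd.DatetimeIndex(trace["timestamp"])
    if not t.is_monotonic_increasing or t.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    light = trace["light"].to_numpy(dtype=float)
    above = light > threshold
    if above.all() or (~above).all():
        warnings.warn("trace never crosses the threshold (all-dark or all-light)")
        return pd.DataFrame(columns=["time", "kind", "flagged"])
    change = np.where(np.diff(above.astype(int)) != 0)[0]
    times, kinds = [], []
    tn = t.asi8.astype(float)
    for i in change:
        # linear interpolation between the straddling samples
        frac = (threshold - light[i]) / (light[i + 1] - light[i])
        times.append(pd.Timestamp(int(tn[i] + frac * (tn[i + 1] - tn[i]))))
        kinds.append("sunrise" if above[i + 1] else "sunset")
    # shading (or nocturnal noise) makes spurious dark/light spells much
    # shorter than any real night or day: delete sunset->sunrise (or
    # sunrise->sunset) pairs closer than the refractory window, repeatedly,
    # flagging the surviving neighbours as suspect.  Real dark/light
    # periods must therefore exceed the window (4 h covers both a boreal
    # breeding summer night and an austral winter day at the latitudes of
    # this system).
    window_ns = refractory_hours * 3.6e12
    tt = np.array([pd.Timestamp(tm).value for tm in times], dtype=float)
    kk = list(kinds)
    flags = [False] * len(kk)
    # crossings alternate rise/fall, so consecutive events always bound one
    # light or dark spell; removing the globally shortest spell first keeps
    # a tiny shading blip from swallowing a genuine twilight next to it
    while len(tt) > 1:
        gaps = np.diff(tt)
        i = int(np.argmin(gaps))
        if gaps[i] > window_ns:
            break
        tt = np.delete(tt, [i, i + 1])
        del kk[i:i + 2]
        del flags[i:i + 2]
        if i > 0:
            flags[i - 1] = True
        if i < len(flags):
            flags[i] = True
    return pd.DataFrame({"time": pd.to_datetime(tt.astype(np.int64)),
                         "kind": kk, "flagged": flags})


def pair_twilights(events: pd.DataFrame) -> pd.DataFrame:
    """Pair each sunrise with the following sunset into local days."""
    pairs = []
    events = events.sort_values("time").reset_index(drop=True)
    for i in range(len(events) - 1):
        if events.loc[i, "kind"] == "sunrise" and events.loc[i + 1, "kind"] == "sunset":
            pairs.append((events.loc[i, "time"], events.loc[i + 1, "time"]))
    return pd.DataFrame(pairs, columns=["sunrise", "sunset"])


def estimate_position(sunrise, sunset, date=None, angle: float = -4.0) -> PositionEstimate:
    """One daily position from a sunrise/sunset pair.

    Longitude comes from the midpoint's offset from Greenwich apparent noon
    (15 deg per hour, equation-of-time corrected); latitude from numerically
    inverting the sunrise equation at the calibration angle for the
    observed day length.  Near an equinox the day length is (almost)
    latitude-independent and the estimate is flagged invalid.
    """
    sunrise, sunset = pd.Timestamp(sunrise), pd.Timestamp(sunset)
    if sunset <= sunrise:
        raise ValueError("sunset must follow sunrise")
    midday = sunrise + (sunset - sunrise) / 2
    if date is None:
        date = midday.normalize()
    date = pd.Timestamp(date)
    day_length = (sunset - sunrise) / pd.Timedelta(hours=1)
    lon = solar.longitude_from_midday(midday, date)
    decl = solar.declination_on(date)
    lat = solar.latitude_from_day_length(day_length, decl, angle)
    if np.isnan(lat):
        reason = "equinox-degenerate" if abs(decl) < 1.5 else "no-root"
        return PositionEstimate(date, float("nan"), lon, day_length, False, reason)
    return PositionEstimate(date, lat, lon, day_length, True)


def estimate_positions(trace: pd.DataFrame, angle: float,
                       threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Daily positions for a whole trace: detect, pair, invert.

    Returns a DataFrame with columns date, latitude, longitude, day_length,
    valid, reason and near-equinox distance (days).
    """
    events = detect_twilights(trace, threshold)
    pairs = pair_twilights(events)
    rows = []
    for _, p in pairs.iterrows():
        est = estimate_position(p["sunrise"], p["sunset"], angle=angle)
        rows.append(est.__dict__)
    pos = pd.DataFrame(rows, columns=["date", "latitude", "longitude",
                                      "day_length", "valid", "reason"])
    if len(pos):
        pos["days_from_equinox"] = [solar.days_from_equinox(d) for d in pos["date"]]
    return pos


def calibrate_sun_elevation(trace: pd.DataFrame, colony_latitude: float,
                            summer_window: tuple = (6, 7),
                            candidates=DEFAULT_ANGLE_CANDIDATES,
                            threshold: float = DEFAULT_THRESHOLD,
                            min_valid: int = 10) -> float:
    """Pick the sun elevation angle whose summer latitudes best match the colony.

    For each candidate angle, estimate latitudes over the summer months at
    the colony (default June-July) and score by the median absolute
    deviation from ``colony_latitude``; the best-scoring angle wins, ties
    broken toward the smaller ``|angle|``.
    """
    candidates = list(candidates)
    if len(candidates) == 1:
        return float(candidates[0])
    scores = []
    for angle in candidates:
        pos = estimate_positions(trace, angle, threshold)
        if len(pos) == 0:
            continue
        summer = pos[pos["valid"] & pd.DatetimeIndex(pos["date"]).month.isin(summer_window)]
        if len(summer) < min_valid:
            continue
        err = float(np.median(np.abs(summer["latitude"] - colony_latitude)))
        scores.append((err, abs(angle), float(angle)))
    if not scores:
        raise ValueError(f"no candidate angle yielded >= {min_valid} valid summer estimates")
    scores.sort()
    return scores[0][2]


def _circular_mean_deg(lon_deg) -> float:
    rad = np.radians(np.asarray(lon_deg, dtype=float))
    s, c = np.nanmean(np.sin(rad)), np.nanmean(np.cos(rad))
    return solar.wrap_longitude(np.degrees(np.arctan2(s, c)))


def smooth_positions(positions: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Centred rolling mean over valid estimates; circular in longitude.

    Invalid rows keep their flag (no silent imputation); valid rows are
    replaced by the window mean over valid members only.  Longitude is
    averaged as a unit vector so the date line and the 0-meridian behave.
    """
    out = positions.copy().reset_index(drop=True)
    lat = out["latitude"].where(out["valid"]).to_numpy(dtype=float)
    lon = np.radians(out["longitude"].where(out["valid"]).to_numpy(dtype=float))
    lat_s = pd.Series(lat).rolling(window, center=True, min_periods=1).mean()
    sin_s = pd.Series(np.sin(lon)).rolling(window, center=True, min_periods=1).mean()
    cos_s = pd.Series(np.cos(lon)).rolling(window, center=True, min_periods=1).mean()
    lon_s = solar.wrap_longitude(np.degrees(np.arctan2(sin_s, cos_s)))
    valid = out["valid"].to_numpy(dtype=bool)
    out.loc[valid, "latitude"] = lat_s[valid]
    out.loc[valid, "longitude"] = np.asarray(lon_s)[valid]
    return out


def remove_outliers_iqr(values) -> np.ndarray:
    """Tukey-fence filter: keep values inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Values exactly on a fence are retained.  Fewer than 4 values cannot
    support quartiles and are returned unfiltered with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 4:
        warnings.warn("fewer than 4 values; IQR filter skipped")
        return v
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return v[(v >= lo) & (v <= hi)]


def iqr_mask(values) -> np.ndarray:
    """Boolean keep-mask version of :func:`remove_outliers_iqr` (NaN -> drop)."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 4:
        return ok
    q1, q3 = np.percentile(v[ok], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return ok & (v >= lo) & (v <= hi)


def mean_monthly_position(positions: pd.DataFrame, month: int = 1,
                          min_estimates: int = 5,
                          equinox_mask_days: float = 15.0) -> dict:
    """Mean position for one calendar month after Tukey filtering.

    Latitude is an arithmetic mean, longitude a circular mean.  Returns a
    dict with latitude, longitude, n and reason ('' when ok); both
    coordinates are NaN when fewer than ``min_estimates`` survive.
    """
    sel = positions[positions["valid"] & (pd.DatetimeIndex(positions["date"]).month == month)]
    if "days_from_equinox" in sel.columns:
        sel = sel[sel["days_from_equinox"] > equinox_mask_days]
    keep = iqr_mask(sel["latitude"]) & iqr_mask(sel["longitude"])
    sel = sel[keep]
    if len(sel) < min_estimates:
        return {"latitude": float("nan"), "longitude": float("nan"),
                "n": int(len(sel)), "reason": "too-few-valid-estimates"}
    return {"latitude": float(np.mean(sel["latitude"])),
            "longitude": _circular_mean_deg(sel["longitude"]),
            "n": int(len(sel)), "reason": ""}
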