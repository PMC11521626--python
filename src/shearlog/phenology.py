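"""Migration phenology from longitude series.

Longitude is used rather than full position because it is insensitive to
equinox error.  Where the original workflow relied on visual inspection of
longitude-versus-time plots, this module fixes an explicit, reproducible
rule: a migration is a run of at least ``min_run_days`` (K) consecutive
days displaced more than ``displacement_deg`` (D) from the reference
longitude, and the start/end dates are read off the monotone departure or
approach limb adjoining the qualifying run.  K and D are configuration,
validated by recovery against simulated tracks with known dates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import wrap_longitude

DEFAULT_MIN_RUN_DAYS = 5
DEFAULT_DISPLACEMENT_DEG = 10.0
HOME_TOL_DEG = 1.0


@dataclass
class PhenologyDates:
    southbound_start: pd.Timestamp | None
    northbound_start: pd.Timestamp | None
    northbound_end: pd.Timestamp | None
    method: str = "longitude-run"
    confidence: str = "ok"
    reason: str = ""

    def ordered(self) -> bool:
        if any(d is None for d in (self.southbound_start, self.northbound_start,
                                   self.northbound_end)):
            return False
        return self.southbound_start < self.northbound_start < self.northbound_end


def _first_run(mask: np.ndarray, k: int) -> int | None:
    """Index where the first run of >= k consecutive True begins."""
    count = 0
    for i, m in enumerate(mask):
        count = count + 1 if m else 0
        if count >= k:
            return i - k + 1
    return None


def detect_migration_dates(longitudes: pd.DataFrame, colony_longitude: float,
                           min_run_days: int = DEFAULT_MIN_RUN_DAYS,
                           displacement_deg: float = DEFAULT_DISPLACEMENT_DEG,
                           home_tol_deg: float = HOME_TOL_DEG) -> PhenologyDates:
    """Southbound start, northbound start and colony return from longitudes.

    Parameters
    ----------
    longitudes : DataFrame with columns ``date`` and ``longitude`` spanning
        one annual cycle (smoothed; date-ordered daily series).
    colony_longitude : reference longitude of the breeding colony.

    Southbound start is the last day within ``home_tol_deg`` of the colony
    longitude immediately before the first sustained displaced run (i.e.
    the departure day); northbound start is, symmetrically, the last day on
    the winter-longitude plateau before the sustained return; northbound
    end is the first day back within ``home_tol_deg`` of the colony.
    Missing/unqualified runs yield None dates with a reason.
    """
    df = longitudes.dropna(subset=["longitude"]).sort_values("date").reset_index(drop=True)
    if len(df) < 2 * min_run_days:
        return PhenologyDates(None, None, None, confidence="missing", reason="track too short")
    dates = pd.DatetimeIndex(df["date"])
    disp = np.asarray(wrap_longitude(df["longitude"].to_numpy(dtype=float) - colony_longitude))
    if np.all(np.abs(disp) <= displacement_deg):
        return PhenologyDates(None, None, None, confidence="missing",
                              reason="no sustained displacement from colony")
    side = np.sign(disp[int(np.argmax(np.abs(disp)))])
    toward = side * disp  # positive when displaced toward the non-breeding side

    away = toward > displacement_deg
    r0 = _first_run(away, min_run_days)
    if r0 is None:
        return PhenologyDates(None, None, None, confidence="missing",
                              reason="no qualifying displaced run")
    # walk back along the departure limb to the last day near the colony
    i = r0
    while i > 0 and toward[i - 1] < toward[i] and toward[i - 1] > home_tol_deg:
        i -= 1
    south = dates[i - 1] if i > 0 and toward[i - 1] <= home_tol_deg else dates[i]
    south_confidence = "ok" if i > 0 else "truncated-start"

    # winter plateau: median displacement over displaced days
    plateau = float(np.median(toward[away]))
    # sustained movement back toward the colony after the plateau is reached
    reached = _first_run(toward > plateau - home_tol_deg, 1)
    back = (plateau - toward > displacement_deg) & (np.arange(len(toward)) > (reached or 0))
    m = _first_run(back, min_run_days)
    if m is None:
        return PhenologyDates(south, None, None, confidence="incomplete",
                              reason="no northbound run")
    i = m
    while i > 0 and toward[i - 1] > toward[i] and plateau - toward[i - 1] > home_tol_deg:
        i -= 1
    north_start = dates[i - 1] if i > 0 and plateau - toward[i - 1] <= home_tol_deg else dates[i]

    # colony return: first sustained stay within D, then first day within home_tol
    near = np.abs(disp) < displacement_deg
    near[: m] = False
    t = _first_run(near, min_run_days)
    if t is None:
        return PhenologyDates(south, north_start, None, confidence="incomplete",
                              reason="no colony return")
    j = t
    while j < len(toward) and np.abs(disp[j]) > home_tol_deg:
        j += 1
    north_end = dates[j] if j < len(toward) else dates[t]
    result = PhenologyDates(south, north_start, north_end, confidence=south_confidence)
    if not result.ordered():
        return PhenologyDates(None, None, None, confidence="missing",
                              reason="detected dates out of order")
    return result
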