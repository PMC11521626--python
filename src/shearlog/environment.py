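"""Climate-index covariates and the chlorophyll-peak latitude.

Non-breeding conditions are summarised by the Southern Oscillation Index
averaged over October-December (the peak of an El Nino / La Nina event and
of Southwest-Atlantic phytoplankton blooms); breeding-ground conditions by
the winter (December-March) and summer (June-August) North Atlantic
Oscillation means, with December assigned to the following year's winter.
Resource distribution on the Patagonian shelf is summarised by the
latitude of maximum January chlorophyll-a inside a fixed box (35-45 deg S,
59-63 deg W).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SOI_MONTHS = (10, 11, 12)
NAO_WINTER_MONTHS = (12, 1, 2, 3)
NAO_SUMMER_MONTHS = (6, 7, 8)
PATAGONIAN_BOX = ((-45.0, -35.0), (-63.0, -59.0))  # (lat range, lon range)


def seasonal_index_mean(series: pd.DataFrame, months, december_to_next: bool = False,
                        years=None) -> pd.DataFrame:
    """Arithmetic seasonal mean of a monthly climate index.

    ``series`` has columns year, month, value.  With ``december_to_next``,
    December is assigned to the following year's season (the Dec-Mar winter
    spans the year boundary).  Years missing any requested month get NaN
    with a reason.
    """
    months = list(months)
    lookup = {(int(r.year), int(r.month)): float(r.value) for r in series.itertuples()}
    if years is None:
        years = sorted(series["year"].unique())
        if december_to_next:
            years = sorted(set(years) | {y + 1 for y in years})
    rows = []
    for year in years:
        vals = []
        complete = True
        for m in months:
            src_year = year - 1 if (december_to_next and m == 12) else year
            v = lookup.get((int(src_year), int(m)))
            if v is None:
                complete = False
                break
            vals.append(v)
        if complete:
            rows.append({"year": year, "value": float(np.mean(vals)), "reason": ""})
        else:
            rows.append({"year": year, "value": float("nan"), "reason": "missing month"})
    return pd.DataFrame(rows)


def soi_ond(series: pd.DataFrame, years=None) -> pd.DataFrame:
    """October-December SOI mean per year."""
    return seasonal_index_mean(series, SOI_MONTHS, years=years)


def nao_winter(series: pd.DataFrame, years=None) -> pd.DataFrame:
    """December-March NAO mean; December belongs to the following winter."""
    return seasonal_index_mean(series, NAO_WINTER_MONTHS, december_to_next=True, years=years)


def nao_summer(series: pd.DataFrame, years=None) -> pd.DataFrame:
    """June-August NAO mean per year."""
    return seasonal_index_mean(series, NAO_SUMMER_MONTHS, years=years)


@dataclass
class ChlorophyllField:
    """Gridded chlorophyll-a (mg m^-3) for one month."""

    latitudes: np.ndarray   # strictly monotone 1-D grid
    longitudes: np.ndarray
    values: np.ndarray      # (lat, lon), >= 0 or NaN
    year: int
    month: int

    def __post_init__(self):
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for g in (self.latitudes, self.longitudes):
            if len(g) > 1 and not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
                raise ValueError("grid must be strictly monotone")
        if self.values.shape != (len(self.latitudes), len(self.longitudes)):
            raise ValueError("values must be (lat, lon) shaped")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("chlorophyll values must be >= 0")


def chlorophyll_peak_latitude(field: ChlorophyllField, box=PATAGONIAN_BOX,
                              method: str = "zonal-mean",
                              min_coverage: float = 0.5):
    """Latitude of maximum chlorophyll inside a lat/lon box.

    ``method='zonal-mean'`` (default) averages each latitude row across the
    box longitudes (missing-aware) before taking the argmax, which is
    robust to single-pixel blooms; ``'max-cell'`` takes the single highest
    cell.  Ties go to the latitude nearest the box centre.  Returns
    (latitude, reason); latitude is NaN when under ``min_coverage``
    non-missing cells.
    """
    (lat_lo, lat_hi), lon_r = sorted(box[0]), sorted(box[1])
    lon_lo, lon_hi = lon_r
    li = np.where((field.latitudes >= lat_lo) & (field.latitudes <= lat_hi))[0]
    lj = np.where((field.longitudes >= lon_lo) & (field.longitudes <= lon_hi))[0]
    if len(li) == 0 or len(lj) == 0:
        return float("nan"), "box does not overlap grid"
    sub = field.values[np.ix_(li, lj)]
    if np.isfinite(sub).mean() < min_coverage:
        return float("nan"), "insufficient coverage"
    lats = field.latitudes[li]
    centre = 0.5 * (lat_lo + lat_hi)
    if method == "zonal-mean":
        with np.errstate(invalid="ignore"):
            profile = np.nanmean(sub, axis=1)
    elif method == "max-cell":
        profile = np.nanmax(sub, axis=1)
    else:
        raise ValueError(f"unknown peak method: {method!r}")
    best = np.nanmax(profile)
    cand = lats[np.isclose(profile, best, rtol=0, atol=0) | (profile == best)]
    winner = cand[np.argmin(np.abs(cand - centre))]
    return float(winner), ""
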