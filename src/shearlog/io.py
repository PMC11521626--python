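"""Readers and writers for logger and climate file dialects.

Light traces: a plain CSV dialect (``timestamp`` ISO-8601 UTC, ``light``
float) and the BAS-style ``.lig`` dialect (four comma-separated columns:
status flag, ``DD/MM/YYYY HH:MM:SS``, seconds counter, light).  Immersion:
CSV (``bin_start``, ``score``) and the matching ``.act`` dialect.  Climate
indices: long CSV (year, month, value) or the NOAA monthly-table layout
(one row per year, twelve month columns).  Chlorophyll grids travel as
long CSV (lat, lon, value) per field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .environment import ChlorophyllField

_MONTHS = ["jan", "feb", "mar", "apr", "may", "jun",
           "jul", "aug", "sep", "oct", "nov", "dec"]


def read_light_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"], float_precision="round_trip")
    return df[["timestamp", "light"]]


def write_light_csv(trace: pd.DataFrame, path):
    trace.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_lig(path) -> pd.DataFrame:
    """BAS .lig: ``ok,DD/MM/YYYY HH:MM:SS,seconds,light`` per line."""
    df = pd.read_csv(path, header=None,
                     names=["status", "datetime", "seconds", "light"], float_precision="round_trip")
    ts = pd.to_datetime(df["datetime"], format="%d/%m/%Y %H:%M:%S")
    return pd.DataFrame({"timestamp": ts, "light": df["light"].astype(float)})


def read_immersion_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["bin_start"], float_precision="round_trip")
    return df[["bin_start", "score"]]


def write_immersion_csv(trace: pd.DataFrame, path):
    trace.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_act(path) -> pd.DataFrame:
    """BAS .act: ``ok,DD/MM/YYYY HH:MM:SS,seconds,score`` per line."""
    df = pd.read_csv(path, header=None,
                     names=["status", "datetime", "seconds", "score"], float_precision="round_trip")
    ts = pd.to_datetime(df["datetime"], format="%d/%m/%Y %H:%M:%S")
    return pd.DataFrame({"bin_start": ts, "score": df["score"].astype(int)})


def read_index_csv(path, name: str = "") -> pd.DataFrame:
    """Monthly climate index: long (year, month, value) or NOAA wide table."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower().strip(): c for c in df.columns}
    if "month" in cols and "value" in cols:
        out = df.rename(columns={cols["year"]: "year", cols["month"]: "month",
                                 cols["value"]: "value"})
        return out[["year", "month", "value"]].astype({"year": int, "month": int})
    # NOAA layout: YEAR, JAN..DEC
    month_cols = [cols[m] for m in _MONTHS if m in cols]
    if len(month_cols) != 12 or "year" not in cols:
        raise ValueError(f"unrecognised index layout in {path}")
    long = df.melt(id_vars=[cols["year"]], value_vars=month_cols,
                   var_name="month_name", value_name="value")
    long["month"] = long["month_name"].str.lower().map(
        {m: i + 1 for i, m in enumerate(_MONTHS)})
    long = long.rename(columns={cols["year"]: "year"})
    return long[["year", "month", "value"]].sort_values(
        ["year", "month"]).reset_index(drop=True).astype({"year": int, "month": int})


def write_index_csv(series: pd.DataFrame, path):
    series[["year", "month", "value"]].to_csv(path, index=False)


def read_chlorophyll_csv(path, year: int, month: int = 1) -> ChlorophyllField:
    """Long-format grid: columns lat, lon, value (one row per cell)."""
    df = pd.read_csv(path, float_precision="round_trip")
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    values = (df.pivot_table(index="lat", columns="lon", values="value")
                .reindex(index=lats, columns=lons).to_numpy())
    return ChlorophyllField(latitudes=lats, longitudes=lons, values=values,
                            year=year, month=month)


def write_chlorophyll_csv(field: ChlorophyllField, path):
    lat, lon = np.meshgrid(field.latitudes, field.longitudes, indexing="ij")
    pd.DataFrame({"lat": lat.ravel(), "lon": lon.ravel(),
                  "value": field.values.ravel()}).to_csv(path, index=False)
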