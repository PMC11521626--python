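"""Synthetic bird-years with known ground truth.

Emulates the raw material of a multi-year shearwater geolocator study:
trans-equatorial tracks between a North Atlantic colony and the Patagonian
shelf, light traces consistent with solar elevation at the true position
(plus shading), 10-min saltwater-immersion scores generated from a
day/night-structured behaviour process (flight / forage / rest, night
colony visits, multi-day incubation stints), an ENSO-like AR(1) climate
index that shifts winter latitude with a known within-individual slope,
and January chlorophyll fields with a programmed zonal ridge.

Everything is deterministic given ``SimConfig.seed``: each bird-year draws
from its own RNG stream derived from (seed, bird, year).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import solar

STATES = ("flight", "forage", "rest")
BINS_PER_DAY = 144  # 10-min bins
KM_PER_DEG = 111.32


@dataclass(frozen=True)
class Colony:
    name: str
    latitude: float
    longitude: float


def _default_day_matrix():
    # rows/cols ordered flight, forage, rest; per 10-min bin
    return np.array([
        [0.70, 0.25, 0.05],
        [0.15, 0.75, 0.10],
        [0.10, 0.30, 0.60],
    ])


def _default_night_matrix():
    return np.array([
        [0.50, 0.05, 0.45],
        [0.05, 0.50, 0.45],
        [0.02, 0.03, 0.95],
    ])


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults describe a Skomer-like colony with a mid-Patagonian-shelf
    non-breeding ground, a within-individual latitude response of
    -0.30 deg per index unit on top of between-individual spread, and a
    standardised AR(1) climate index.
    """

    n_birds: int = 20
    n_years: int = 5
    colony: Colony = field(default_factory=lambda: Colony("Skomer", 51.74, -5.29))
    first_year: int = 2008

    winter_latitude_base: float = -42.0
    winter_longitude_base: float = -58.0
    within_slope: float = -0.30          # deg latitude per index unit
    between_sd: float = 1.5              # deg, bird-level offset
    winter_noise_sd: float = 0.5         # deg, residual year-level noise

    index_ar1: float = 0.5
    index_innovation_sd: float = 1.0

    # phenology day-of-year means/sds: southbound start, northbound start, northbound end
    phenology_means: tuple = (255.0, 60.0, 85.0)
    phenology_sds: tuple = (7.0, 7.0, 5.0)
    southbound_duration: float = 20.0    # days colony -> winter ground

    day_matrix: np.ndarray = field(default_factory=_default_day_matrix)
    night_matrix: np.ndarray = field(default_factory=_default_night_matrix)
    night_visit_prob: float = 0.30       # P(chick-rearing night spent at colony)
    incubation_stint_days: int = 5
    incubation_month: int = 6

    # chlorophyll ridge: peak latitude = ridge_base + ridge_slope * OND index
    # + noise; negative slope: the bloom (and the birds) shift north when
    # the index goes negative (El Nino)
    ridge_base: float = -40.0
    ridge_slope: float = -2.4
    ridge_noise_sd: float = 0.3
    chl_lat_step: float = 0.25
    chl_lon_step: float = 0.5

    staggered_deployment: bool = True   # birds tracked in contiguous 2-4 year blocks

    light_interval_min: int = 5
    light_max: float = 64.0
    light_threshold_angle: float = -4.0  # sun elevation at which light crosses 10
    light_slope: float = 1.0             # logistic steepness per degree elevation
    shading_prob: float = 0.05

    seed: int = 0

    def __post_init__(self):
        for m in (self.day_matrix, self.night_matrix):
            m = np.asarray(m, dtype=float)
            if m.shape != (3, 3) or np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("transition matrix rows must be non-negative and sum to 1")
        for p in (self.night_visit_prob, self.shading_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lat in (self.colony.latitude, self.winter_latitude_base):
            if not -90.0 <= lat <= 90.0:
                raise ValueError("latitudes must lie in [-90, 90]")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset (all bird-years)."""

    config: SimConfig
    positions: pd.DataFrame      # bird, year, date, latitude, longitude
    phenology: pd.DataFrame      # bird, year, southbound_start, northbound_start, northbound_end
    winter: pd.DataFrame         # bird, year, winter_latitude, winter_longitude, index_ond
    states: pd.DataFrame         # bird, year, bin_start, state (incl. 'colony')
    visits: pd.DataFrame         # bird, year, night_date, is_visit
    incubation: pd.DataFrame     # bird, year, start, end
    index: pd.DataFrame          # year, month, value
    chlorophyll: dict            # year -> ChlorophyllField-like (environment.ChlorophyllField)
    chl_peaks: pd.DataFrame      # year, peak_latitude


def rng_for(cfg: SimConfig, *key) -> np.random.Generator:
    """Independent RNG stream for (seed, *key); reproducible under parallelism."""
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# climate index and chlorophyll
# ---------------------------------------------------------------------------

def simulate_index(cfg: SimConfig) -> pd.DataFrame:
    """Monthly AR(1) climate index over the study years (plus one lead year)."""
    rng = rng_for(cfg, 1)
    years = range(cfg.first_year - 1, cfg.first_year + cfg.n_years + 1)
    rows = []
    x = 0.0
    for year in years:
        for month in range(1, 13):
            innov = rng.normal(0.0, cfg.index_innovation_sd) if cfg.index_innovation_sd > 0 else 0.0
            x = cfg.index_ar1 * x + innov
            rows.append((year, month, x))
    return pd.DataFrame(rows, columns=["year", "month", "value"])


def index_ond(index: pd.DataFrame, year: int) -> float:
    """October-December mean of the index for ``year`` (the ENSO covariate)."""
    sel = index[(index["year"] == year) & (index["month"].isin([10, 11, 12]))]
    return float(sel["value"].mean())


def simulate_environment(cfg: SimConfig):
    """(monthly index series, {year: January chlorophyll field}, programmed peaks).

    Each January field carries a single zonal ridge whose peak latitude is
    ``ridge_base + ridge_slope * OND-index(previous year) + noise``; the OND
    window of year y sets conditions for the January of y+1, matching how
    the index covariate is aligned downstream.
    """
    from .environment import ChlorophyllField  # local import to avoid a cycle

    index = simulate_index(cfg)
    rng = rng_for(cfg, 2)
    lats = np.arange(-55.0, -25.0 + 1e-9, cfg.chl_lat_step)
    lons = np.arange(-70.0, -50.0 + 1e-9, cfg.chl_lon_step)
    fields, peaks = {}, []
    for year in range(cfg.first_year, cfg.first_year + cfg.n_years + 1):
        idx = index_ond(index, year - 1)
        peak = cfg.ridge_base + cfg.ridge_slope * idx
        if cfg.ridge_noise_sd > 0:
            peak += rng.normal(0.0, cfg.ridge_noise_sd)
        ridge = 0.2 + 5.0 * np.exp(-0.5 * ((lats - peak) / 2.0) ** 2)
        values = np.tile(ridge[:, None], (1, len(lons)))
        values = values * (1.0 + 0.05 * rng.standard_normal(values.shape))
        np.clip(values, 0.0, None, out=values)
        fields[year] = ChlorophyllField(latitudes=lats, longitudes=lons,
                                        values=values, year=year, month=1)
        peaks.append((year, peak))
    return index, fields, pd.DataFrame(peaks, columns=["year", "peak_latitude"])


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _year_dates(cfg: SimConfig, year: int) -> pd.DatetimeIndex:
    """A bird-year runs 1 July of ``year`` to 30 June of ``year + 1``."""
    return pd.date_range(f"{year}-07-01", f"{year + 1}-06-30", freq="D")


def simulate_track(cfg: SimConfig, bird: int, year: int, index: pd.DataFrame | None = None):
    """Daily true positions plus true phenology for one bird-year.

    Returns (positions DataFrame [date, latitude, longitude], phenology dict,
    winter dict).  Winter latitude is
    ``winter_latitude_base + within_slope * OND-index + bird offset + noise``.
    """
    if index is None:
        index = simulate_index(cfg)
    rng = rng_for(cfg, 3, bird, year)
    bird_rng = rng_for(cfg, 4, bird)
    offset = bird_rng.normal(0.0, cfg.between_sd) if cfg.between_sd > 0 else 0.0

    mu = cfg.phenology_means
    sd = cfg.phenology_sds
    if not (mu[1] < mu[2] and mu[1] + 365 > mu[0] + cfg.southbound_duration):
        raise ValueError("phenology dates out of calendar order")
    south_doy = mu[0] + (rng.normal(0.0, sd[0]) if sd[0] > 0 else 0.0)
    north_start_doy = mu[1] + (rng.normal(0.0, sd[1]) if sd[1] > 0 else 0.0)
    north_end_doy = mu[2] + (rng.normal(0.0, sd[2]) if sd[2] > 0 else 0.0)
    # an unlucky draw may invert the northbound leg; clamp it to at least
    # 10 days so ordering holds and no day jumps > 1500 km
    north_end_doy = max(north_end_doy, north_start_doy + 10.0)

    south_start = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=round(south_doy) - 1)
    south_end = south_start + pd.Timedelta(days=round(cfg.southbound_duration))
    north_start = pd.Timestamp(f"{year + 1}-01-01") + pd.Timedelta(days=round(north_start_doy) - 1)
    north_end = pd.Timestamp(f"{year + 1}-01-01") + pd.Timedelta(days=round(north_end_doy) - 1)
    if not (south_start < south_end < north_start < north_end):
        raise ValueError("phenology dates out of calendar order")

    idx_val = index_ond(index, year)
    w_lat = cfg.winter_latitude_base + cfg.within_slope * idx_val + offset
    w_lon = cfg.winter_longitude_base
    if cfg.winter_noise_sd > 0:
        w_lat += rng.normal(0.0, cfg.winter_noise_sd)
        w_lon += rng.normal(0.0, cfg.winter_noise_sd)

    dates = _year_dates(cfg, year)
    lat = np.full(len(dates), cfg.colony.latitude)
    lon = np.full(len(dates), cfg.colony.longitude)
    for i, d in enumerate(dates):
        if south_start < d < south_end:
            f = (d - south_start) / (south_end - south_start)
            lat[i] = cfg.colony.latitude + f * (w_lat - cfg.colony.latitude)
            lon[i] = cfg.colony.longitude + f * (w_lon - cfg.colony.longitude)
        elif south_end <= d <= north_start:
            lat[i], lon[i] = w_lat, w_lon
        elif north_start < d < north_end:
            f = (d - north_start) / (north_end - north_start)
            lat[i] = w_lat + f * (cfg.colony.latitude - w_lat)
            lon[i] = w_lon + f * (cfg.colony.longitude - w_lon)
    positions = pd.DataFrame({"date": dates, "latitude": lat, "longitude": lon})
    phen = {"southbound_start": south_start, "northbound_start": north_start,
            "northbound_end": north_end}
    winter = {"winter_latitude": w_lat, "winter_longitude": w_lon, "index_ond": idx_val}
    return positions, phen, winter


# ---------------------------------------------------------------------------
# light
# ---------------------------------------------------------------------------

def light_from_elevation(elev, cfg: SimConfig):
    """Logistic light response: crosses 10 units exactly at the configured
    threshold sun elevation angle, saturating at ``light_max`` (clipped like
    a real logger)."""
    e0 = cfg.light_threshold_angle + np.log(cfg.light_max / 10.0 - 1.0) / cfg.light_slope
    return cfg.light_max / (1.0 + np.exp(-cfg.light_slope * (np.asarray(elev) - e0)))


def simulate_light(positions: pd.DataFrame, cfg: SimConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Light trace sampled every ``light_interval_min`` minutes along the track.

    Light is a monotone (logistic) function of solar elevation at the true
    position; shading events multiply a sample down (never up), so light
    stays >= 0 and never exceeds the clean curve.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    step = pd.Timedelta(minutes=cfg.light_interval_min)
    t0 = pd.Timestamp(positions["date"].iloc[0])
    t1 = pd.Timestamp(positions["date"].iloc[-1]) + pd.Timedelta(days=1) - step
    times = pd.date_range(t0, t1, freq=step)
    day_idx = ((times - t0) / pd.Timedelta(days=1)).astype(int)
    day_idx = np.clip(day_idx, 0, len(positions) - 1)
    lats = positions["latitude"].to_numpy()[day_idx]
    lons = positions["longitude"].to_numpy()[day_idx]
    elev = solar.solar_elevation(times, lats, lons)
    light = light_from_elevation(elev, cfg)
    if cfg.shading_prob > 0:
        shaded = rng.random(len(light)) < cfg.shading_prob
        light = np.where(shaded, light * 0.02, light)
    return pd.DataFrame({"timestamp": times, "light": light})


# ---------------------------------------------------------------------------
# behaviour and immersion
# ---------------------------------------------------------------------------

def simulate_states(positions: pd.DataFrame, phen: dict, cfg: SimConfig,
                    rng: np.random.Generator):
    """True behaviour per 10-min bin: Markov flight/forage/rest with separate
    day/night matrices, overridden by colony occupancy.

    Colony overrides: whole nights ashore with probability
    ``night_visit_prob`` while the bird is resident at the colony
    (chick-rearing), and one all-dry incubation stint of
    ``incubation_stint_days`` starting early in ``incubation_month``.
    Returns (states DataFrame [bin_start, state], visit nights DataFrame,
    incubation intervals list).
    """
    t0 = pd.Timestamp(positions["date"].iloc[0])
    n_days = len(positions)
    times = pd.date_range(t0, periods=n_days * BINS_PER_DAY, freq="10min")
    day_idx = np.repeat(np.arange(n_days), BINS_PER_DAY)
    lats = positions["latitude"].to_numpy()[day_idx]
    lons = positions["longitude"].to_numpy()[day_idx]
    mid = times + pd.Timedelta(minutes=5)
    is_day = solar.solar_elevation(mid, lats, lons) > 0.0

    at_colony_day = (positions["latitude"].to_numpy() == cfg.colony.latitude) & (
        positions["longitude"].to_numpy() == cfg.colony.longitude)

    # night ids: bins belong to the night that starts at the most recent sunset
    # (approximate by date of the preceding noon)
    night_date = (times - pd.Timedelta(hours=12)).normalize()

    n = len(times)
    state = np.zeros(n, dtype=int)
    state[0] = 2  # start resting
    u = rng.random(n)
    day_cum = np.cumsum(cfg.day_matrix, axis=1)
    night_cum = np.cumsum(cfg.night_matrix, axis=1)
    for i in range(1, n):
        cum = day_cum if is_day[i] else night_cum
        state[i] = np.searchsorted(cum[state[i - 1]], u[i])

    labels = np.array(STATES, dtype=object)[state]

    colony_mask = np.zeros(n, dtype=bool)
    visit_rows = []
    # night colony visits while resident at the colony
    unique_nights = pd.DatetimeIndex(sorted(set(night_date)))
    night_codes = pd.DatetimeIndex(night_date)
    for nd in unique_nights:
        d_off = int((nd - t0.normalize()) / pd.Timedelta(days=1))
        if not (0 <= d_off < n_days and at_colony_day[d_off]):
            continue
        sel = (night_codes == nd) & ~is_day
        if not sel.any():
            continue
        visited = rng.random() < cfg.night_visit_prob
        if visited:
            idx = np.where(sel)[0]
            # bird reaches the colony within ~2 h of dark; earlier bins stay at sea
            arrive = idx[0] + rng.integers(0, 13)
            colony_mask[idx[idx >= arrive]] = True
        visit_rows.append((nd, visited))
    visits = pd.DataFrame(visit_rows, columns=["night_date", "is_visit"])

    # one incubation stint: consecutive all-dry days in the incubation month
    incub = []
    year1 = t0.year + 1
    start = pd.Timestamp(year=year1, month=cfg.incubation_month, day=5)
    d_off = int((start - t0.normalize()) / pd.Timedelta(days=1))
    if 0 <= d_off < n_days and at_colony_day[d_off]:
        stop = start + pd.Timedelta(days=int(cfg.incubation_stint_days))
        in_stint = (times >= start) & (times < stop)
        colony_mask |= np.asarray(in_stint)
        incub.append((start, stop))

    labels = labels.copy()
    labels[colony_mask] = "colony"
    states = pd.DataFrame({"bin_start": times, "state": labels})
    return states, visits, incub


def simulate_immersion(states: pd.DataFrame, cfg: SimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """10-min immersion scores from true states.

    flight -> 0 (dry on the wing), rest -> 200 (sat on the water the whole
    bin), forage -> uniform integer in [1, 199], colony/burrow -> 0.
    """
    lab = states["state"].to_numpy()
    known = np.isin(lab, list(STATES) + ["colony"])
    if not known.all():
        bad = sorted(set(lab[~known]))
        raise ValueError(f"unknown state label(s): {bad}")
    score = np.zeros(len(lab), dtype=int)
    score[lab == "rest"] = 200
    forage = lab == "forage"
    score[forage] = rng.integers(1, 200, size=int(forage.sum()))
    return pd.DataFrame({"bin_start": states["bin_start"], "score": score})


# ---------------------------------------------------------------------------
# whole-dataset orchestration
# ---------------------------------------------------------------------------

def deployment_years(cfg: SimConfig, bird: int) -> list:
    """Years a bird carries a logger: a contiguous block of 2-4 study years.

    Mirrors real multi-year programmes where loggers are redeployed on a
    rotating subset of the marked population, so different birds span
    different (overlapping) year windows.  With ``staggered_deployment``
    off, every bird is tracked every year.
    """
    years = list(range(cfg.first_year, cfg.first_year + cfg.n_years))
    if not cfg.staggered_deployment or cfg.n_years <= 2:
        return years
    rng = rng_for(cfg, 7, bird)
    length = int(rng.integers(2, min(4, cfg.n_years) + 1))
    start = int(rng.integers(0, cfg.n_years - length + 1))
    return years[start:start + length]


def simulate_bird_year(cfg: SimConfig, bird: int, year: int,
                       index: pd.DataFrame | None = None, sensors: bool = True) -> dict:
    """Everything for one bird-year: track, truth and (optionally) sensors.

    Sensor streams are keyed by (seed, bird, year) so any bird-year can be
    regenerated independently and reproducibly.
    """
    if index is None:
        index = simulate_index(cfg)
    positions, phen, winter = simulate_track(cfg, bird, year, index)
    out = {"positions": positions, "phenology": phen, "winter": winter}
    if sensors:
        rng = rng_for(cfg, 5, bird, year)
        states, visits, incub = simulate_states(positions, phen, cfg, rng)
        out["states"] = states
        out["visits"] = visits
        out["incubation"] = incub
        out["immersion"] = simulate_immersion(states, cfg, rng)
        out["light"] = simulate_light(positions, cfg, rng_for(cfg, 6, bird, year))
    return out


def simulate_dataset(cfg: SimConfig, with_sensors: bool = True) -> SimTruth:
    """Simulate every bird-year: tracks and truth always; light and immersion
    traces are attached to the returned frames by the pipeline when
    ``with_sensors`` (they are large, so callers that only need truth can
    skip them via per-bird-year calls instead)."""
    index, chl, peaks = simulate_environment(cfg)
    pos_rows, phen_rows, winter_rows = [], [], []
    state_rows, visit_rows, incub_rows = [], [], []
    for bird in range(cfg.n_birds):
        for year in deployment_years(cfg, bird):
            positions, phen, winter = simulate_track(cfg, bird, year, index)
            p = positions.copy()
            p.insert(0, "year", year)
            p.insert(0, "bird", bird)
            pos_rows.append(p)
            phen_rows.append({"bird": bird, "year": year, **phen})
            winter_rows.append({"bird": bird, "year": year, **winter})
            if with_sensors:
                rng = rng_for(cfg, 5, bird, year)
                states, visits, incub = simulate_states(positions, phen, cfg, rng)
                s = states.copy()
                s.insert(0, "year", year)
                s.insert(0, "bird", bird)
                state_rows.append(s)
                v = visits.copy()
                v.insert(0, "year", year)
                v.insert(0, "bird", bird)
                visit_rows.append(v)
                for a, b in incub:
                    incub_rows.append({"bird": bird, "year": year, "start": a, "end": b})
    empty = pd.DataFrame()
    return SimTruth(
        config=cfg,
        positions=pd.concat(pos_rows, ignore_index=True),
        phenology=pd.DataFrame(phen_rows),
        winter=pd.DataFrame(winter_rows),
        states=pd.concat(state_rows, ignore_index=True) if state_rows else empty,
        visits=pd.concat(visit_rows, ignore_index=True) if visit_rows else empty,
        incubation=pd.DataFrame(incub_rows, columns=["bird", "year", "start", "end"]),
        index=index,
        chlorophyll=chl,
        chl_peaks=peaks,
    )
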