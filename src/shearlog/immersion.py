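"""Behaviour from saltwater-immersion scores.

A leg-mounted logger samples conductivity every 3 s and sums wet samples
per 10-min bin, giving a score from 0 (completely dry) to 200 (completely
immersed).  At sea, score 0 is flight, 200 is rest on the water and
anything in between is foraging.  Time ashore at the colony is recognised
separately: by day, a continuous dry spell of >= 6 h means the bird is in
its burrow; by night, nights ashore are separated from nights at sea by a
two-component Gaussian mixture over nightly wet-event counts (nights
ashore sit in the drier component).  Multi-day all-dry spells (>= 3 days)
are incubation stints and count as evidence of a breeding attempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

BIN_MINUTES = 10
BINS_PER_DAY = 144
MAX_SCORE = 200  # 10 min / 3 s samples per bin

STATE_DRY = "dry"            # flight
STATE_WET = "wet"            # rest / preen on the water
STATE_INTERMEDIATE = "intermediate"  # foraging
STATE_COLONY = "colony"


def _check_scores(score: np.ndarray):
    bad = np.where((score < 0) | (score > MAX_SCORE))[0]
    if len(bad):
        raise ValueError(f"immersion score out of [0, {MAX_SCORE}] at bin {bad[0]}")


def classify_states(trace: pd.DataFrame, at_sea_mask=None) -> pd.DataFrame:
    """Three-state classification of at-sea bins.

    ``trace`` has columns ``bin_start`` and ``score``; ``at_sea_mask``
    (optional boolean per bin) marks bins already attributed to the colony,
    which are labelled ``colony`` instead of a sea state.
    """
    score = trace["score"].to_numpy(dtype=int)
    _check_scores(score)
    state = np.full(len(score), STATE_INTERMEDIATE, dtype=object)
    state[score == 0] = STATE_DRY
    state[score == MAX_SCORE] = STATE_WET
    if at_sea_mask is not None:
        state[~np.asarray(at_sea_mask, dtype=bool)] = STATE_COLONY
    return pd.DataFrame({"bin_start": trace["bin_start"], "state": state})


def _zero_runs(score: np.ndarray):
    """(start, stop) index pairs of maximal all-zero runs; stop exclusive."""
    iszero = np.concatenate([[0], (score == 0).astype(int), [0]])
    d = np.diff(iszero)
    starts = np.where(d == 1)[0]
    stops = np.where(d == -1)[0]
    return list(zip(starts, stops))


def detect_daytime_burrow(trace: pd.DataFrame, sunrise, sunset,
                          min_dry_hours: float = 6.0) -> list:
    """Daytime burrow intervals for one day.

    Maximal runs of score-0 bins lying fully within [sunrise, sunset] and
    lasting >= ``min_dry_hours`` (run length = bins x 10 min) are returned
    as (start, stop) timestamp pairs.
    """
    t = pd.DatetimeIndex(trace["bin_start"])
    score = trace["score"].to_numpy(dtype=int)
    _check_scores(score)
    step = pd.Timedelta(minutes=BIN_MINUTES)
    inside = (t >= pd.Timestamp(sunrise)) & ((t + step) <= pd.Timestamp(sunset))
    masked = np.where(inside, score, -1)  # break runs at night bins
    min_bins = int(round(min_dry_hours * 60 / BIN_MINUTES))
    out = []
    for a, b in _zero_runs(np.where(masked == 0, 0, 1)):
        if b - a >= min_bins:
            out.append((t[a], t[b - 1] + step))
    return out


def count_night_wet_events(trace: pd.DataFrame, night: tuple):
    """Number of 10-min bins with any immersion between sunset and sunrise.

    ``night`` is the (sunset, next sunrise) pair; a bin belongs to the
    night if its start falls inside.  Returns None for an empty night
    (polar day / no bins).
    """
    sunset, sunrise = map(pd.Timestamp, night)
    t = pd.DatetimeIndex(trace["bin_start"])
    sel = (t >= sunset) & (t < sunrise)
    if not sel.any():
        return None
    score = trace["score"].to_numpy(dtype=int)[sel]
    _check_scores(score)
    return int((score > 0).sum())


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian EM fit; component 0 is the drier."""

    means: tuple
    sds: tuple
    weights: tuple
    log_likelihood: float
    iterations: int
    converged: bool
    seed: int = 0
    ll_history: list = field(default_factory=list, repr=False)

    def posterior_dry(self, x):
        """Responsibility of the drier (lower-mean) component at x."""
        x = np.asarray(x, dtype=float)
        p0 = self.weights[0] * norm.pdf(x, self.means[0], self.sds[0])
        p1 = self.weights[1] * norm.pdf(x, self.means[1], self.sds[1])
        with np.errstate(invalid="ignore"):
            post = p0 / (p0 + p1)
        # far in a tail both densities underflow; assign by nearer mean
        nearer_dry = np.abs(x - self.means[0]) < np.abs(x - self.means[1])
        return np.where(np.isnan(post), np.where(nearer_dry, 1.0, 0.0), post)


def fit_night_mixture(counts, seed: int = 0, tol: float = 1e-8,
                      max_iter: int = 1000) -> MixtureFit:
    """Two-component Gaussian EM over nightly wet-event counts.

    Initialised from the 25th/75th percentiles with a shared spread and
    equal weights; iterates E/M until the log-likelihood gain drops below
    ``tol``.  Components are ordered so the drier (lower) mean comes
    first.  Raises on degenerate input (all counts equal, or a component
    spread collapsing below 1e-6).
    """
    x = np.asarray(counts, dtype=float)
    if len(x) < 20:
        raise ValueError("need >= 20 nights to fit the mixture")
    if np.ptp(x) == 0:
        raise ValueError("degenerate mixture: all counts identical")
    mu = np.percentile(x, [25, 75]).astype(float)
    if mu[0] == mu[1]:
        mu = np.array([x.min(), x.max()], dtype=float)
    sd = np.full(2, max(np.std(x) / 2.0, 1e-3))
    w = np.array([0.5, 0.5])
    ll_history = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = w * norm.pdf(x[:, None], mu[None, :], sd[None, :])
        tot = dens.sum(axis=1)
        tot = np.where(tot <= 0, np.finfo(float).tiny, tot)
        ll = float(np.log(tot).sum())
        ll_history.append(ll)
        resp = dens / tot[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk <= 0):
            raise ValueError("degenerate mixture: empty component")
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if np.any(sd < 1e-6):
            raise ValueError("degenerate mixture: variance collapse")
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
    order = np.argsort(mu)
    return MixtureFit(
        means=tuple(mu[order]), sds=tuple(sd[order]), weights=tuple(w[order]),
        log_likelihood=ll_history[-1], iterations=it, converged=converged,
        seed=seed, ll_history=ll_history,
    )


def classify_night_visits(summaries: pd.DataFrame, fit: MixtureFit) -> pd.DataFrame:
    """Attach colony-visit calls to per-night summaries.

    A night is a colony visit when the posterior probability of the drier
    mixture component exceeds 0.5 at its wet-event count.
    """
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    out = summaries.copy()
    post = fit.posterior_dry(out["wet_event_count"].to_numpy(dtype=float))
    out["posterior_dry_component"] = post
    out["is_visit"] = post > 0.5
    return out


def detect_incubation(trace: pd.DataFrame, min_days: float = 3.0):
    """(evidence, intervals): maximal all-dry runs of >= ``min_days``.

    A continuous dry spell of at least 3 days (432 bins) is characteristic
    of an incubation stint and taken as evidence of a breeding attempt.
    """
    t = pd.DatetimeIndex(trace["bin_start"])
    score = trace["score"].to_numpy(dtype=int)
    _check_scores(score)
    min_bins = int(round(min_days * BINS_PER_DAY))
    step = pd.Timedelta(minutes=BIN_MINUTES)
    intervals = [(t[a], t[b - 1] + step) for a, b in _zero_runs(score)
                 if b - a >= min_bins]
    return len(intervals) > 0, intervals


@dataclass
class ForagingEffort:
    period: str
    foraging_hours: float        # mean foraging hours per day
    daylight_hours: float        # day length at the relevant position
    proportion: float
    n_days: int
    flagged: bool = False        # proportion > 1 (night-foraging overflow)


def foraging_effort(states: pd.DataFrame, is_day, daylight_hours: float,
                    period: str = "") -> ForagingEffort:
    """Day-length-standardised foraging effort over a period.

    ``states`` are behaviour bins for the period, ``is_day`` a boolean per
    bin (daylight at the bird's position), ``daylight_hours`` the day
    length at the bird's mean position for the period.  Foraging hours are
    10/60 h per intermediate daylight bin, averaged per day; the
    proportion divides by day length and is flagged (never clipped) when
    above 1.
    """
    if daylight_hours <= 0 or np.isnan(daylight_hours):
        raise ValueError("zero daylight: effort undefined")
    is_day = np.asarray(is_day, dtype=bool)
    sel = (states["state"].to_numpy() == STATE_INTERMEDIATE) & is_day
    dates = pd.DatetimeIndex(states["bin_start"]).normalize()
    n_days = dates.nunique()
    if n_days == 0:
        raise ValueError("empty period")
    hours_per_day = float(sel.sum()) * BIN_MINUTES / 60.0 / n_days
    prop = hours_per_day / daylight_hours
    return ForagingEffort(period=period, foraging_hours=hours_per_day,
                          daylight_hours=float(daylight_hours),
                          proportion=prop, n_days=int(n_days), flagged=prop > 1.0)


def count_colony_visits(night_summaries: pd.DataFrame, month: int = 8,
                        burrow_days=None, include_burrow_days: bool = True):
    """Distinct colony-visit nights in a month, plus stand-alone burrow days.

    ``night_summaries`` must carry ``night_date`` and ``is_visit`` (from
    :func:`classify_night_visits`).  A day with a daytime burrow interval
    whose adjoining nights are already visits adds nothing (one continuous
    night+day+night stay counts once per night); an isolated burrow day
    adds one.  Returns None when the month is not covered.
    """
    nights = night_summaries.copy()
    nights["night_date"] = pd.DatetimeIndex(nights["night_date"])
    sel = nights[nights["night_date"].dt.month == month]
    if len(sel) == 0:
        return None
    count = int(sel["is_visit"].sum())
    if include_burrow_days and burrow_days is not None:
        visit_nights = set(sel.loc[sel["is_visit"], "night_date"].dt.normalize())
        for day in pd.DatetimeIndex(burrow_days).normalize():
            if day.month != month:
                continue
            prev_night = day - pd.Timedelta(days=1)
            if day not in visit_nights and prev_night not in visit_nights:
                count += 1
    return count
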