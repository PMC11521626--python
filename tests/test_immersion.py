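"""Immersion-score behaviour classification, mixture model, effort."""

import numpy as np
import pandas as pd
import pytest

from shearlog import immersion as imm


def trace_of(scores, start="2009-08-01 00:00"):
    times = pd.date_range(start, periods=len(scores), freq="10min")
    return pd.DataFrame({"bin_start": times, "score": list(scores)})


class TestClassifyStates:
    @pytest.mark.parametrize("score,state", [
        (0, imm.STATE_DRY), (200, imm.STATE_WET), (57, imm.STATE_INTERMEDIATE),
        (1, imm.STATE_INTERMEDIATE), (199, imm.STATE_INTERMEDIATE),
    ])
    def test_score_maps_to_state(self, score, state):
        out = imm.classify_states(trace_of([score]))
        assert out["state"][0] == state

    def test_colony_mask_overrides(self):
        out = imm.classify_states(trace_of([0, 200]), at_sea_mask=[True, False])
        assert list(out["state"]) == [imm.STATE_DRY, imm.STATE_COLONY]

    def test_out_of_range_score_names_the_bin(self):
        with pytest.raises(ValueError, match="bin 1"):
            imm.classify_states(trace_of([0, 201]))

    def test_every_bin_gets_exactly_one_state(self, rng):
        scores = rng.integers(0, 201, size=imm.BINS_PER_DAY)
        out = imm.classify_states(trace_of(scores))
        assert len(out) == imm.BINS_PER_DAY
        counts = out["state"].value_counts()
        assert counts.sum() == imm.BINS_PER_DAY


class TestDaytimeBurrow:
    sunrise = pd.Timestamp("2009-08-01 05:00")
    sunset = pd.Timestamp("2009-08-01 20:00")

    def _day(self, zero_bins, offset_bins=0):
        scores = [100] * imm.BINS_PER_DAY
        start = 31 + offset_bins  # 05:10 by default, inside daylight
        for i in range(zero_bins):
            scores[start + i] = 0
        return trace_of(scores)

    def test_36_zero_bins_is_a_burrow_stay(self):
        out = imm.detect_daytime_burrow(self._day(36), self.sunrise, self.sunset)
        assert len(out) == 1
        start, stop = out[0]
        assert stop - start == pd.Timedelta(hours=6)

    def test_35_zero_bins_is_not(self):
        assert imm.detect_daytime_burrow(self._day(35), self.sunrise, self.sunset) == []

    def test_dry_run_straddling_sunset_does_not_count(self):
        # 6 h of zeros starting 17:10: crosses the 20:00 sunset
        out = imm.detect_daytime_burrow(self._day(36, offset_bins=72),
                                        self.sunrise, self.sunset)
        assert out == []


class TestNightWetEvents:
    night = (pd.Timestamp("2009-08-01 21:00"), pd.Timestamp("2009-08-02 05:00"))

    def test_all_dry_night_counts_zero(self):
        assert imm.count_night_wet_events(trace_of([0] * 144), self.night) == 0

    def test_mixed_scores_count_wet_bins(self):
        scores = [0] * 126 + [0, 3, 0, 200, 17, 0] + [0] * 12
        assert imm.count_night_wet_events(trace_of(scores), self.night) == 3

    def test_fully_wet_8h_night_counts_48(self):
        assert imm.count_night_wet_events(trace_of([200] * 288), self.night) == 48

    def test_night_without_bins_is_missing(self):
        night = (pd.Timestamp("2010-01-01 22:00"), pd.Timestamp("2010-01-02 04:00"))
        assert imm.count_night_wet_events(trace_of([0] * 10), night) is None


@pytest.fixture(scope="module")
def counts():
    rng = np.random.default_rng(7)
    dry = rng.normal(2, 1, 200)
    sea = rng.normal(30, 5, 200)
    return np.concatenate([dry, sea]), np.r_[np.ones(200), np.zeros(200)]


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(2, 1, 200).clip(0), rng.normal(30, 5, 200)])
    return imm.fit_night_mixture(x, seed=0)


class TestNightMixture:
    def test_recovers_means_within_one(self, counts):
        x, _ = counts
        fit = imm.fit_night_mixture(x, seed=0)
        assert fit.converged
        assert fit.means[0] == pytest.approx(2.0, abs=1.0)
        assert fit.means[1] == pytest.approx(30.0, abs=1.0)

    def test_loglik_nondecreasing_every_iteration(self, counts):
        fit = imm.fit_night_mixture(counts[0], seed=0)
        diffs = np.diff(fit.ll_history)
        assert (diffs >= -1e-9).all()

    def test_beats_grid_search_oracle(self, counts):
        """EM log-likelihood >= a brute grid over (mu1, mu2, sigma, w)."""
        from scipy.stats import norm

        x = counts[0][:200]
        fit = imm.fit_night_mixture(x, seed=0)
        best = -np.inf
        for m1 in np.linspace(0, 10, 11):
            for m2 in np.linspace(20, 40, 11):
                for s in (1.0, 2.5, 5.0, 8.0):
                    for w in (0.3, 0.5, 0.7):
                        ll = np.log(w * norm.pdf(x, m1, s)
                                    + (1 - w) * norm.pdf(x, m2, s)).sum()
                        best = max(best, ll)
        assert fit.log_likelihood >= best - 1e-6

    def test_matches_sklearn_reference(self, counts):
        from sklearn.mixture import GaussianMixture

        x = counts[0]
        fit = imm.fit_night_mixture(x, seed=0)
        gm = GaussianMixture(2, covariance_type="diag", tol=1e-8,
                             random_state=0, n_init=3).fit(x[:, None])
        ref = np.sort(gm.means_.ravel())
        assert fit.means[0] == pytest.approx(ref[0], abs=0.3)
        assert fit.means[1] == pytest.approx(ref[1], abs=0.3)

    def test_responsibility_half_at_equidistant_point(self):
        fit = imm.MixtureFit(means=(2.0, 30.0), sds=(3.0, 3.0), weights=(0.5, 0.5),
                             log_likelihood=0.0, iterations=1, converged=True)
        assert fit.posterior_dry(16.0) == pytest.approx(0.5)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="identical"):
            imm.fit_night_mixture([5.0] * 30)
        with pytest.raises(ValueError, match=">= 20"):
            imm.fit_night_mixture([1.0, 2.0])


class TestVisitClassification:
    def test_zero_count_is_a_visit_and_high_count_is_not(self, fit):
        nights = pd.DataFrame({"night_date": pd.date_range("2009-08-01", periods=2),
                               "wet_event_count": [0, 45]})
        out = imm.classify_night_visits(nights, fit)
        assert bool(out["is_visit"][0]) and not bool(out["is_visit"][1])
        assert out["posterior_dry_component"].between(0, 1).all()

    def test_accuracy_at_4sd_separation(self, fit):
        rng = np.random.default_rng(9)
        truth = rng.random(400) < 0.4
        x = np.where(truth, rng.normal(2, 1, 400).clip(0), rng.normal(30, 5, 400))
        nights = pd.DataFrame({"night_date": pd.date_range("2009-06-01", periods=400),
                               "wet_event_count": x})
        out = imm.classify_night_visits(nights, fit)
        assert (out["is_visit"] == truth).mean() >= 0.95

    def test_visit_call_monotone_in_count(self, fit):
        grid = pd.DataFrame({"night_date": pd.date_range("2009-08-01", periods=49),
                             "wet_event_count": np.arange(49)})
        out = imm.classify_night_visits(grid, fit)
        v = out["is_visit"].astype(int).to_numpy()
        assert (np.diff(v) <= 0).all()


class TestIncubation:
    def test_432_zero_bins_is_evidence(self):
        ev, ivs = imm.detect_incubation(trace_of([0] * 432 + [100]))
        assert ev and len(ivs) == 1

    def test_431_zero_bins_is_not(self):
        ev, _ = imm.detect_incubation(trace_of([0] * 431 + [100]))
        assert not ev

    def test_wet_bin_splitting_two_short_runs_is_not(self):
        ev, _ = imm.detect_incubation(trace_of([0] * 288 + [200] + [0] * 288))
        assert not ev


class TestForagingEffort:
    def _states(self, n_intermediate, n_total=144):
        scores = [57] * n_intermediate + [200] * (n_total - n_intermediate)
        return imm.classify_states(trace_of(scores))

    def test_every_daylight_bin_foraging_is_proportion_one(self):
        states = self._states(84)
        is_day = np.r_[np.ones(84, bool), np.zeros(60, bool)]
        eff = imm.foraging_effort(states, is_day, daylight_hours=14.0)
        assert eff.proportion == pytest.approx(1.0)
        assert not eff.flagged

    def test_half_of_daylight_foraging_is_half(self):
        states = self._states(42)
        is_day = np.r_[np.ones(84, bool), np.zeros(60, bool)]
        eff = imm.foraging_effort(states, is_day, daylight_hours=14.0)
        assert eff.proportion == pytest.approx(0.5)

    def test_21_bins_over_14h_day_is_quarter(self):
        states = self._states(21)
        is_day = np.ones(144, bool)
        eff = imm.foraging_effort(states, is_day, daylight_hours=14.0)
        assert eff.proportion == pytest.approx(0.25)

    def test_overflow_flagged_not_clipped(self):
        states = self._states(144)
        eff = imm.foraging_effort(states, np.ones(144, bool), daylight_hours=12.0)
        assert eff.proportion > 1.0 and eff.flagged

    def test_zero_daylight_raises(self):
        with pytest.raises(ValueError, match="daylight"):
            imm.foraging_effort(self._states(10), np.ones(144, bool), 0.0)


class TestColonyVisitCount:
    def _nights(self, visits):
        n = len(visits)
        return pd.DataFrame({"night_date": pd.date_range("2009-08-01", periods=n),
                             "wet_event_count": 0, "is_visit": visits})

    def test_no_visits_is_zero(self):
        assert imm.count_colony_visits(self._nights([False] * 10)) == 0

    def test_ten_visit_nights_count_ten(self):
        assert imm.count_colony_visits(self._nights([True] * 10)) == 10

    def test_burrow_day_between_visit_nights_not_double_counted(self):
        nights = self._nights([True, True, False])
        count = imm.count_colony_visits(
            nights, burrow_days=[pd.Timestamp("2009-08-02")])
        assert count == 2

    def test_isolated_burrow_day_adds_one(self):
        nights = self._nights([False] * 5)
        count = imm.count_colony_visits(
            nights, burrow_days=[pd.Timestamp("2009-08-03")])
        assert count == 1

    def test_uncovered_month_is_missing(self):
        assert imm.count_colony_visits(self._nights([True]), month=1) is None
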