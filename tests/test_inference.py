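"""Path analysis, mixed models, subject centring, GLMs."""

import numpy as np
import pandas as pd
import pytest

from shearlog import inference as inf


def chain_data(rng, n=300, b_ab=0.5, b_bc=-0.7):
    a = rng.normal(size=n)
    b = b_ab * a + rng.normal(size=n)
    c = b_bc * b + rng.normal(size=n)
    return pd.DataFrame({"a": a, "b": b, "c": c})


class TestPathModel:
    def test_cyclic_spec_rejected(self):
        with pytest.raises(ValueError, match="recursive"):
            inf.PathModelSpec(["a", "b"], [("a", "b"), ("b", "a")])

    def test_saturated_model_fits_perfectly(self, rng):
        data = chain_data(rng)
        spec = inf.PathModelSpec(["a", "b", "c"],
                                 [("a", "b"), ("a", "c"), ("b", "c")])
        res = inf.fit_path_model(spec, data)
        assert res.fit["chisq"] == 0.0
        assert res.fit["df"] == 0
        assert res.fit["cfi"] == 1.0
        assert res.fit["srmr"] == pytest.approx(0.0, abs=1e-8)

    def test_edges_equal_equationwise_ols(self, rng):
        """Recursive ML estimates coincide with per-equation least squares."""
        import statsmodels.api as sm

        data = chain_data(rng)
        spec = inf.PathModelSpec(["a", "b", "c"], [("a", "b"), ("b", "c")])
        res = inf.fit_path_model(spec, data, standardize=False)
        for (yv, xs) in [("b", ["a"]), ("c", ["b"])]:
            ols = sm.OLS(data[yv], sm.add_constant(data[xs])).fit()
            got = res.edges[res.edges["target"] == yv].set_index("source")["beta"]
            for xv in xs:
                assert got[xv] == pytest.approx(ols.params[xv], abs=1e-8)

    def test_badly_misspecified_model_has_low_clipped_cfi(self, rng):
        # data is the chain a->b->c but the model routes c through a only,
        # leaving the strong b-c covariance unreproduced
        data = chain_data(rng, b_ab=0.9, b_bc=-0.9)
        spec = inf.PathModelSpec(["a", "b", "c"], [("a", "c")])
        res = inf.fit_path_model(spec, data)
        assert res.fit["chisq"] > res.fit["df"]
        # well under the ~0.9 good-fit convention, and inside the clip range
        assert 0.0 <= res.fit["cfi"] < 0.8
        assert 0.0 <= res.fit["tli"] <= 1.0

    def test_standardized_betas_match_correlation_for_single_edge(self, rng):
        data = chain_data(rng)
        spec = inf.PathModelSpec(["a", "b"], [("a", "b")])
        res = inf.fit_path_model(spec, data[["a", "b"]], standardize=True)
        r = np.corrcoef(data["a"], data["b"])[0, 1]
        assert res.edges["beta"][0] == pytest.approx(r, abs=1e-10)

    def test_figure_graph_recovers_generating_coefficients(self, rng):
        spec = inf.figure_graph_spec()
        data = simulate_from_graph(spec, rng, n=400)
        res = inf.fit_path_model(spec, data, standardize=False)
        merged = res.edges.merge(TRUE_BETAS, on=["source", "target"])
        assert len(merged) == len(spec.edges)
        inside = np.abs(merged["beta"] - merged["true"]) <= 2.5 * merged["se"]
        assert inside.all()


TRUE_BETAS = pd.DataFrame(
    [("soi", "january_latitude", -0.33),
     ("january_latitude", "january_foraging", -0.25),
     ("august_foraging_prev", "january_foraging", 0.4),
     ("january_foraging", "august_foraging", 0.22),
     ("august_foraging", "august_visits", 0.35),
     ("southbound_start", "northbound_start", 0.35),
     ("northbound_start", "northbound_end", 0.7),
     ("august_foraging_prev", "southbound_start", 0.0),
     ("soi", "northbound_start", 0.0),
     ("january_foraging", "northbound_start", 0.0)],
    columns=["source", "target", "true"])


def simulate_from_graph(spec, rng, n=200, betas=TRUE_BETAS, noise_sd=0.8):
    """Draw from the recursive linear system with unit-variance exogenous."""
    lookup = {(r.source, r.target): r.true for r in betas.itertuples()}
    data = {}
    for v in spec.topological_order():
        parents = spec.parents(v)
        x = rng.normal(0, 1.0 if not parents else noise_sd, size=n)
        for p in parents:
            x = x + lookup[(p, v)] * data[p]
        data[v] = x
    return pd.DataFrame(data)


class TestBonferroni:
    def test_single_test_keeps_alpha(self):
        assert inf.sem_bonferroni_alpha(1, 0.3) == 0.05

    def test_fully_correlated_tests_need_no_correction(self):
        assert inf.sem_bonferroni_alpha(10, 1.0) == 0.05

    def test_k10_r_half(self):
        assert inf.sem_bonferroni_alpha(10, 0.5) == pytest.approx(0.05 / np.sqrt(10))

    def test_independent_tests_recover_plain_bonferroni(self):
        assert inf.sem_bonferroni_alpha(8, 0.0) == pytest.approx(0.05 / 8)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            inf.sem_bonferroni_alpha(5, 1.2)


def lmm_data(rng, n_groups=30, per=8, slope=2.0, group_sd=1.0, resid_sd=1.0):
    g = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=len(g))
    y = slope * x + rng.normal(0, group_sd, n_groups)[g] + rng.normal(0, resid_sd, len(g))
    return pd.DataFrame({"y": y, "x": x, "g": g})


class TestLMM:
    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        d = lmm_data(rng)
        fit = inf.fit_lmm(d, "y", ["x"], "g", n_boot=0)
        ref = smf.mixedlm("y ~ x", d, groups=d["g"]).fit(reml=True)
        assert fit.beta["x"] == pytest.approx(ref.params["x"], abs=1e-5)
        assert fit.beta["(intercept)"] == pytest.approx(ref.params["Intercept"], abs=1e-5)
        assert fit.tau2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
        assert fit.sigma2 == pytest.approx(float(ref.scale), abs=1e-4)

    def test_zero_group_variance_estimate_is_small(self, rng):
        # under a true zero the REML estimate sits at or near the boundary
        d = lmm_data(rng, group_sd=0.0)
        fit = inf.fit_lmm(d, "y", ["x"], "g", n_boot=0)
        assert fit.tau2 <= 0.1 * fit.sigma2

    def test_boundary_variance_flagged_with_warning(self, rng):
        # pure within-group noise (group means exactly zero) has negative
        # intraclass correlation: the variance estimate pins to the boundary
        d = lmm_data(rng, group_sd=0.0, slope=0.0)
        d["y"] = d["y"] - d.groupby("g")["y"].transform("mean")
        with pytest.warns(UserWarning, match="boundary"):
            fit = inf.fit_lmm(d, "y", ["x"], "g", n_boot=0)
        assert fit.singular
        assert fit.tau2 == pytest.approx(0.0, abs=1e-8)

    def test_single_group_rejected(self, rng):
        d = lmm_data(rng, n_groups=1)
        with pytest.raises(ValueError, match="groups"):
            inf.fit_lmm(d, "y", ["x"], "g", n_boot=0)

    def test_bootstrap_ci_reproducible_under_seed(self, rng):
        d = lmm_data(rng)
        a = inf.fit_lmm(d, "y", ["x"], "g", n_boot=50, seed=9)
        b = inf.fit_lmm(d, "y", ["x"], "g", n_boot=50, seed=9)
        pd.testing.assert_frame_equal(a.boot_ci, b.boot_ci)

    def test_bootstrap_ci_covers_true_slope(self, rng):
        d = lmm_data(rng, n_groups=50, per=10)
        fit = inf.fit_lmm(d, "y", ["x"], "g", focal="x", n_boot=300, seed=3)
        lo, hi = fit.boot_ci.set_index("term").loc["x", ["lower", "upper"]]
        assert lo <= 2.0 <= hi

    def test_lrt_type_I_error_near_nominal(self):
        """Null-effect LRT rejects at about the nominal 5% rate."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            d = lmm_data(rng, n_groups=15, per=4, slope=0.0)
            fit = inf.fit_lmm(d, "y", ["x"], "g", focal="x", n_boot=0)
            rejections += fit.lrt["p"] < 0.05
        assert 0.03 <= rejections / n_sims <= 0.08


def centring_data(rng, n_birds=60, per=5, within=-0.30, between=-0.77,
                  bird_sd=0.5, resid_sd=0.5):
    """Simulate from the centred model itself: the between effect acts on
    the observed per-bird mean (what the decomposition actually fits)."""
    birds = np.repeat(np.arange(n_birds), per)
    x = rng.normal(0, 1, n_birds)[birds] + rng.normal(0, 1, len(birds))
    xbar_obs = pd.Series(x).groupby(birds).transform("mean").to_numpy()
    y = (between * xbar_obs + within * (x - xbar_obs)
         + rng.normal(0, bird_sd, n_birds)[birds] + rng.normal(0, resid_sd, len(birds)))
    return pd.DataFrame({"x": x, "y": y, "bird": birds})


class TestSubjectCentring:
    def test_recovers_within_and_between_slopes_unbiasedly(self):
        """Estimates centre on the programmed slopes across replicates and the
        decomposition matches the closed-form OLS on deviations."""
        rng = np.random.default_rng(5)
        within_est, between_est = [], []
        for i in range(30):
            d = centring_data(rng)
            res = inf.subject_centring(d, "x", "y", "bird", n_boot=20, seed=i)
            within_est.append(res.within)
            between_est.append(res.between)
            assert res.within == pytest.approx(-0.30, abs=0.2)
            assert res.between == pytest.approx(-0.77, abs=0.4)
        assert np.mean(within_est) == pytest.approx(-0.30, abs=0.03)
        assert np.mean(between_est) == pytest.approx(-0.77, abs=0.07)

    def test_difference_equals_between_minus_within(self):
        rng = np.random.default_rng(6)
        d = centring_data(rng)
        res = inf.subject_centring(d, "x", "y", "bird", n_boot=50, seed=1)
        assert res.difference == pytest.approx(res.between - res.within, abs=1e-6)

    def test_covariate_reconstruction_identity(self):
        rng = np.random.default_rng(7)
        d = centring_data(rng)
        means = d.groupby("bird")["x"].transform("mean")
        np.testing.assert_allclose(means + (d["x"] - means), d["x"])

    def test_constant_within_bird_covariate_rejected(self):
        d = pd.DataFrame({"x": np.repeat([1.0, 2.0, 3.0], 4),
                          "y": np.arange(12, dtype=float),
                          "bird": np.repeat([0, 1, 2], 4)})
        with pytest.raises(ValueError, match="within"):
            inf.subject_centring(d, "x", "y", "bird")


class TestSkipGLM:
    def test_no_effect_gives_near_zero_beta(self, rng):
        n = 400
        d = pd.DataFrame({"january_foraging": rng.normal(0.5, 0.1, n),
                          "skipped_breeding": rng.random(n) < 0.5})
        out = inf.fit_skip_glm(d)
        assert not out["separation"]
        assert abs(out["beta"]) <= 2 * out["se"] + 1.0

    def test_steep_slope_recovered_within_2se(self):
        """Logit slope 12 at n = 200: estimate within 2 SE in >= 90% of runs."""
        rng = np.random.default_rng(8)
        hits, runs = 0, 150
        for _ in range(runs):
            x = rng.uniform(0, 1, 200)
            p = 1 / (1 + np.exp(-(12.0 * (x - 0.5))))
            d = pd.DataFrame({"january_foraging": x,
                              "skipped_breeding": rng.random(200) < p})
            out = inf.fit_skip_glm(d)
            if not out["separation"] and abs(out["beta"] - 12.0) <= 2 * out["se"]:
                hits += 1
        assert hits / runs >= 0.90

    def test_single_class_rejected(self):
        d = pd.DataFrame({"january_foraging": [0.1, 0.2, 0.3],
                          "skipped_breeding": [True, True, True]})
        with pytest.raises(ValueError, match="classes"):
            inf.fit_skip_glm(d)

    def test_complete_separation_flagged(self):
        d = pd.DataFrame({"january_foraging": np.r_[np.zeros(20), np.ones(20)],
                          "skipped_breeding": np.r_[np.zeros(20), np.ones(20)] > 0.5})
        out = inf.fit_skip_glm(d)
        assert out["separation"]


class TestVisitsMassValidation:
    def _records(self, rng, slope=2.0, date_effect=0.0, n_burrows=25, per=3):
        burrow = np.repeat(np.arange(n_burrows), per)
        visits = rng.integers(0, 20, len(burrow)).astype(float)
        date = rng.integers(210, 250, len(burrow)).astype(float)
        mass = (380 + slope * visits + date_effect * date
                + rng.normal(0, 12, n_burrows)[burrow] + rng.normal(0, 8, len(burrow)))
        return pd.DataFrame({"peak_mass": mass, "august_visits": visits,
                             "peak_date": date, "burrow": burrow})

    def test_visit_slope_recovered_within_ci(self):
        rng = np.random.default_rng(12)
        fit = inf.validate_visits_vs_mass(self._records(rng), n_boot=400, seed=2)
        lo, hi = fit.boot_ci.set_index("term").loc["august_visits", ["lower", "upper"]]
        assert lo <= 2.0 <= hi
        assert fit.lrt["p"] < 0.01

    def test_null_date_effect_ci_covers_zero(self):
        rng = np.random.default_rng(13)
        fit = inf.validate_visits_vs_mass(self._records(rng), n_boot=400, seed=2)
        lo, hi = fit.boot_ci.set_index("term").loc["peak_date", ["lower", "upper"]]
        assert lo <= 0.0 <= hi

    def test_constant_visits_rejected(self, rng):
        d = self._records(rng)
        d["august_visits"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            inf.validate_visits_vs_mass(d)
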