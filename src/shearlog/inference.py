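"""The statistical layer: recursive path analysis, mixed models, centring.

Covers four pieces of machinery:

* a covariance-based path analysis over observed variables (a recursive
  linear system, so maximum-likelihood edge estimates coincide with
  equation-wise least squares), with the usual SEM fit indices
  (chi-square/df, CFI, TLI, RMSEA, SRMR) and a Bonferroni adjustment of
  the per-test alpha of the form 0.05 / k**(1 - mean |r|);
* a random-intercept linear mixed model fitted by profiled (RE)ML over
  the variance ratio, with likelihood-ratio tests on ML fits and seeded
  parametric-bootstrap confidence intervals (1000 draws by default);
* the van de Pol & Wright subject-centring decomposition of a covariate
  into between-individual means and within-individual deviations, with a
  difference test via the alternative (raw x, subject mean) parametrisation;
* a binomial GLM for the skipped-breeding supplement and the
  chick-peak-mass validation mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModelSpec", "PathModelResult", "fit_path_model", "figure_graph_spec",
    "sem_bonferroni_alpha", "LMMResult", "fit_lmm", "CenteringResult",
    "subject_centring", "fit_skip_glm", "validate_visits_vs_mass",
]


# ---------------------------------------------------------------------------
# path analysis
# ---------------------------------------------------------------------------

@dataclass
class PathModelSpec:
    """A recursive (acyclic) system of directed edges over observed variables."""

    variables: list
    edges: list  # (source, target) pairs

    def __post_init__(self):
        for s, t in self.edges:
            if s not in self.variables or t not in self.variables:
                raise ValueError(f"edge ({s}, {t}) uses an unknown variable")
        self.topological_order()  # raises if cyclic

    def parents(self, v):
        return [s for s, t in self.edges if t == v]

    def endogenous(self):
        return [v for v in self.variables if self.parents(v)]

    def exogenous(self):
        return [v for v in self.variables if not self.parents(v)]

    def topological_order(self):
        indeg = {v: len(self.parents(v)) for v in self.variables}
        order, ready = [], [v for v in self.variables if indeg[v] == 0]
        while ready:
            v = ready.pop()
            order.append(v)
            for s, t in self.edges:
                if s == v:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        ready.append(t)
        if len(order) != len(self.variables):
            raise ValueError("path model must be recursive (acyclic)")
        return order


@dataclass
class PathModelResult:
    edges: pd.DataFrame          # source, target, beta, se, z, p
    fit: dict                    # chisq, df, chisq_df, cfi, tli, rmsea, srmr, ...
    n: int
    standardized: bool
    implied_cov: pd.DataFrame = field(repr=False, default=None)
    sample_cov: pd.DataFrame = field(repr=False, default=None)


def figure_graph_spec() -> PathModelSpec:
    """The carry-over graph linking climate, non-breeding behaviour and the
    following breeding season.

    Variables are per bird-year: the OND climate index (soi), mean January
    latitude and day-standardised January foraging, the previous August's
    foraging, the following August's foraging and colony visits, and the
    three migration dates.  Non-significant but tested edges (index and
    foraging into migration timing) are part of the model.
    """
    variables = [
        "soi", "january_latitude", "january_foraging", "august_foraging_prev",
        "august_foraging", "august_visits", "southbound_start",
        "northbound_start", "northbound_end",
    ]
    edges = [
        ("soi", "january_latitude"),
        ("january_latitude", "january_foraging"),
        ("august_foraging_prev", "january_foraging"),
        ("january_foraging", "august_foraging"),
        ("august_foraging", "august_visits"),
        ("southbound_start", "northbound_start"),
        ("northbound_start", "northbound_end"),
        ("august_foraging_prev", "southbound_start"),
        ("soi", "northbound_start"),
        ("january_foraging", "northbound_start"),
    ]
    return PathModelSpec(variables=variables, edges=edges)


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with intercept; returns (coef, se_ml, rss)."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise np.linalg.LinAlgError("design is rank deficient")
    resid = y - Xd @ coef
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    cov = np.linalg.inv(Xd.T @ Xd) * sigma2_ml
    se = np.sqrt(np.diag(cov))
    return coef[1:], se[1:], rss


def fit_path_model(spec: PathModelSpec, data: pd.DataFrame,
                   standardize: bool = True) -> PathModelResult:
    """ML estimation of a recursive path model on the observed covariance.

    Complete cases only.  Each endogenous variable is regressed on its
    parents (for a recursive system with uncorrelated errors this is the
    ML solution); the model-implied covariance
    (I - B)^-1 Psi (I - B)^-T is compared with the sample covariance to
    give chi-square = (n - 1) F_ML and the incremental/absolute fit
    indices against the independence baseline.
    """
    cols = spec.variables
    df = data[cols].dropna()
    n = len(df)
    if n <= len(cols):
        raise ValueError("too few complete cases")
    X = df.to_numpy(dtype=float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    p = len(cols)
    idx = {v: i for i, v in enumerate(cols)}
    S = np.cov(X, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(S) < p:
        raise np.linalg.LinAlgError("singular sample covariance")

    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    rows = []
    n_free = 0
    for v in spec.endogenous():
        pa = spec.parents(v)
        yv = X[:, idx[v]]
        Xv = X[:, [idx[q] for q in pa]]
        coef, se, rss = _ols(yv, Xv)
        for q, b, s in zip(pa, coef, se):
            B[idx[v], idx[q]] = b
            z = b / s
            rows.append({"source": q, "target": v, "beta": float(b),
                         "se": float(s), "z": float(z),
                         "p": float(2 * stats.norm.sf(abs(z)))})
        # error variance consistent with the ddof-1 sample covariance so a
        # saturated model reproduces S exactly
        psi[idx[v], idx[v]] = rss / (n - 1)
        n_free += len(pa) + 1
    exo = [idx[v] for v in spec.exogenous()]
    psi[np.ix_(exo, exo)] = S[np.ix_(exo, exo)]
    n_free += len(exo) * (len(exo) + 1) // 2

    inv = np.linalg.inv(np.eye(p) - B)
    sigma = inv @ psi @ inv.T

    sign, logdet_sigma = np.linalg.slogdet(sigma)
    _, logdet_s = np.linalg.slogdet(S)
    f_ml = logdet_sigma - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
    f_ml = max(f_ml, 0.0)
    if f_ml < 1e-10:  # saturated / exactly reproduced covariance
        f_ml = 0.0
    chisq = (n - 1) * f_ml
    dof = p * (p + 1) // 2 - n_free

    # independence baseline
    chisq_b = (n - 1) * (float(np.sum(np.log(np.diag(S)))) - logdet_s)
    dof_b = p * (p - 1) // 2

    d = max(chisq - dof, 0.0)
    d_b = max(chisq_b - dof_b, 0.0)
    cfi = 1.0 if d_b == 0 else float(np.clip(1.0 - d / max(d_b, d), 0.0, 1.0))
    if dof == 0:
        tli = 1.0
    else:
        denom = chisq_b / dof_b - 1.0
        tli = 1.0 if denom <= 0 else float(np.clip(
            (chisq_b / dof_b - chisq / dof) / denom, 0.0, 1.0))
    rmsea = 0.0 if dof == 0 else float(np.sqrt(d / (dof * (n - 1))))
    dnorm = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    resid = (S - sigma) / dnorm
    tri = np.tril_indices(p)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))

    fit_stats = {"chisq": float(chisq), "df": int(dof),
                 "chisq_df": float(chisq / dof) if dof > 0 else float("nan"),
                 "cfi": cfi, "tli": tli, "rmsea": rmsea, "srmr": srmr,
                 "baseline_chisq": float(chisq_b), "baseline_df": int(dof_b)}
    return PathModelResult(
        edges=pd.DataFrame(rows), fit=fit_stats, n=n, standardized=standardize,
        implied_cov=pd.DataFrame(sigma, index=cols, columns=cols),
        sample_cov=pd.DataFrame(S, index=cols, columns=cols),
    )


def sem_bonferroni_alpha(k: int, mean_r: float) -> float:
    """Per-test alpha 0.05 / k**(1 - mean_r) for k correlated tests.

    ``mean_r`` is the mean absolute pairwise correlation among the tested
    variables; fully correlated tests (r = 1) need no correction, fully
    independent ones recover the plain Bonferroni 0.05 / k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= mean_r <= 1.0:
        raise ValueError("mean_r must lie in [0, 1]")
    return 0.05 / k ** (1.0 - mean_r)


# ---------------------------------------------------------------------------
# random-intercept linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    beta: pd.Series
    se: pd.Series
    sigma2: float                # residual variance
    tau2: float                  # random-intercept variance
    loglik: float
    reml: bool
    converged: bool
    singular: bool               # variance estimate at the zero boundary
    n: int
    n_groups: int
    lrt: dict | None = None      # {'term', 'chisq', 'df', 'p'}
    boot_ci: pd.DataFrame | None = None  # term, lower, upper


class _RandomInterceptLMM:
    """Profiled-deviance machinery for y = X beta + b_group + e."""

    def __init__(self, y, X, groups):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        codes, self.group_index = pd.factorize(np.asarray(groups))
        self.codes = codes
        self.g = len(self.group_index)
        order = np.argsort(codes, kind="stable")
        self.order = order
        self.sizes = np.bincount(codes, minlength=self.g)
        self.bounds = np.concatenate([[0], np.cumsum(self.sizes)])

    def _gls(self, lam):
        """beta-hat, weighted RSS, log|V|, X'V^-1 X for V = I + lam Z Z'."""
        Xo, yo = self.X[self.order], self.y[self.order]
        c = lam / (1.0 + lam * self.sizes)
        XtVX = Xo.T @ Xo
        XtVy = Xo.T @ yo
        sum_x = np.add.reduceat(Xo, self.bounds[:-1], axis=0)
        sum_y = np.add.reduceat(yo, self.bounds[:-1])
        XtVX -= (sum_x * c[:, None]).T @ sum_x
        XtVy -= sum_x.T @ (c * sum_y)
        beta = np.linalg.solve(XtVX, XtVy)
        r = yo - Xo @ beta
        sum_r = np.add.reduceat(r, self.bounds[:-1])
        rss = float(r @ r - np.sum(c * sum_r ** 2))
        logdet_v = float(np.sum(np.log1p(lam * self.sizes)))
        return beta, rss, logdet_v, XtVX

    def deviance(self, lam, reml):
        beta, rss, logdet_v, XtVX = self._gls(lam)
        n, p = self.n, self.p
        if reml:
            sigma2 = rss / (n - p)
            _, ld = np.linalg.slogdet(XtVX)
            return (n - p) * (1.0 + np.log(2 * np.pi * sigma2)) + logdet_v + ld
        sigma2 = rss / n
        return n * (1.0 + np.log(2 * np.pi * sigma2)) + logdet_v

    def fit(self, reml=True, tol=1e-8):
        obj = lambda u: self.deviance(np.exp(u), reml)
        res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                                       options={"xatol": tol})
        lam = float(np.exp(res.x))
        dev0 = self.deviance(0.0, reml)
        # a variance ratio below ~1e-5 is numerically the zero boundary
        if dev0 <= res.fun or lam < 1e-5:
            lam, dev = 0.0, dev0
        else:
            dev = float(res.fun)
        beta, rss, _, XtVX = self._gls(lam)
        sigma2 = rss / (self.n - self.p if reml else self.n)
        se = np.sqrt(np.diag(np.linalg.inv(XtVX)) * sigma2)
        return beta, se, sigma2, lam * sigma2, -0.5 * dev, lam

    def simulate(self, beta, sigma2, tau2, rng):
        b = rng.normal(0.0, np.sqrt(max(tau2, 0.0)), size=self.g)
        return self.X @ beta + b[self.codes] + rng.normal(0.0, np.sqrt(sigma2), size=self.n)


def _design(data: pd.DataFrame, terms):
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(dtype=float) for t in terms])
    return X, ["(intercept)"] + list(terms)


def fit_lmm(data: pd.DataFrame, response: str, fixed, group: str,
            reml: bool = True, focal: str | None = None,
            n_boot: int = 1000, seed: int = 0, tol: float = 1e-8) -> LMMResult:
    """Random-intercept LMM with LRT and parametric-bootstrap CIs.

    Parameters
    ----------
    data : one row per observation, complete cases taken on the used columns.
    fixed : list of fixed-effect column names (an intercept is implicit).
    focal : if given, a likelihood-ratio test (ML fits with and without the
        focal term, chi-square with 1 df) and bootstrap CIs are attached.
    n_boot : parametric-bootstrap draws (simulate from the fitted model,
        refit, percentile 2.5/97.5); 0 disables.
    """
    fixed = list(fixed)
    cols = [response] + fixed + [group]
    df = data[cols].dropna()
    if df[group].nunique() < 2:
        raise ValueError("need >= 2 groups for a random intercept")
    y = df[response].to_numpy(dtype=float)
    X, names = _design(df, fixed)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (constant column?)")
    model = _RandomInterceptLMM(y, X, df[group])
    beta, se, sigma2, tau2, loglik, lam = model.fit(reml=reml, tol=tol)
    singular = lam == 0.0
    if singular:
        warnings.warn("random-intercept variance estimated at the zero boundary")
    result = LMMResult(
        beta=pd.Series(beta, index=names), se=pd.Series(se, index=names),
        sigma2=sigma2, tau2=tau2, loglik=loglik, reml=reml, converged=True,
        singular=singular, n=model.n, n_groups=model.g,
    )
    if focal is not None:
        if focal not in fixed:
            raise ValueError(f"focal term {focal!r} not among the fixed effects")
        full_ml = _RandomInterceptLMM(y, X, df[group]).fit(reml=False, tol=tol)
        X0, _ = _design(df, [t for t in fixed if t != focal])
        red_ml = _RandomInterceptLMM(y, X0, df[group]).fit(reml=False, tol=tol)
        chisq = max(2.0 * (full_ml[4] - red_ml[4]), 0.0)
        result.lrt = {"term": focal, "chisq": float(chisq), "df": 1,
                      "p": float(stats.chi2.sf(chisq, 1))}
    if n_boot:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_boot, len(names)))
        for b in range(n_boot):
            ystar = model.simulate(beta, sigma2, tau2, rng)
            m = _RandomInterceptLMM(ystar, X, df[group])
            draws[b] = m.fit(reml=reml, tol=tol)[0]
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        result.boot_ci = pd.DataFrame({"term": names, "lower": lo, "upper": hi})
    return result


# ---------------------------------------------------------------------------
# subject centring
# ---------------------------------------------------------------------------

@dataclass
class CenteringResult:
    between: float
    between_ci: tuple
    within: float
    within_ci: tuple
    difference: float            # between - within
    difference_ci: tuple
    lrt_within: dict
    lrt_between: dict
    n: int
    n_birds: int


def subject_centring(data: pd.DataFrame, x: str, y: str, bird: str,
                     n_boot: int = 1000, seed: int = 0) -> CenteringResult:
    """Within/between decomposition of a covariate in a mixed model.

    The covariate splits exactly into the per-bird mean (between) and the
    deviation from it (within): x = x_bar_j + (x_ij - x_bar_j).  The model
    y ~ between + within + (1 | bird) gives the two slopes; refitting in
    the (x, x_bar_j) parametrisation makes the x_bar_j coefficient equal
    between - within, whose bootstrap CI is the difference test.
    """
    df = data[[x, y, bird]].dropna().copy()
    means = df.groupby(bird)[x].transform("mean")
    df["_between"] = means
    df["_within"] = df[x] - means
    if np.allclose(df["_within"], 0.0):
        raise ValueError("x is constant within every bird: within slope inestimable")
    fit_w = fit_lmm(df, y, ["_between", "_within"], bird, focal="_within",
                    n_boot=n_boot, seed=seed)
    fit_b = fit_lmm(df, y, ["_between", "_within"], bird, focal="_between",
                    n_boot=0, seed=seed)
    # difference parametrisation: y ~ x + x_bar; coef on x_bar = between - within
    df["_raw"] = df[x]
    fit_d = fit_lmm(df, y, ["_raw", "_between"], bird, n_boot=n_boot, seed=seed + 1)
    ci = fit_w.boot_ci.set_index("term")
    ci_d = fit_d.boot_ci.set_index("term")
    return CenteringResult(
        between=float(fit_w.beta["_between"]),
        between_ci=(float(ci.loc["_between", "lower"]), float(ci.loc["_between", "upper"])),
        within=float(fit_w.beta["_within"]),
        within_ci=(float(ci.loc["_within", "lower"]), float(ci.loc["_within", "upper"])),
        difference=float(fit_d.beta["_between"]),
        difference_ci=(float(ci_d.loc["_between", "lower"]), float(ci_d.loc["_between", "upper"])),
        lrt_within=fit_w.lrt, lrt_between=fit_b.lrt,
        n=len(df), n_birds=int(df[bird].nunique()),
    )


# ---------------------------------------------------------------------------
# GLM and validation models
# ---------------------------------------------------------------------------

def fit_skip_glm(data: pd.DataFrame, foraging: str = "january_foraging",
                 skipped: str = "skipped_breeding"):
    """Binomial GLM (logit) of skipped breeding on January foraging effort.

    Returns a dict with beta, se, z, p and a ``separation`` flag; under
    complete separation the ML estimate diverges, so a small-ridge
    penalised fit is reported instead (flagged, Wald statistics NaN).
    """
    import statsmodels.api as sm

    df = data[[foraging, skipped]].dropna()
    yv = df[skipped].astype(float)
    if yv.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(df[[foraging]].astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.GLM(yv, X, family=sm.families.Binomial()).fit()
        if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e4):
            raise RuntimeError("separation suspected")
        return {"beta": float(fit.params[foraging]), "se": float(fit.bse[foraging]),
                "z": float(fit.tvalues[foraging]), "p": float(fit.pvalues[foraging]),
                "separation": False, "n": len(df)}
    except Exception:
        ridge = sm.Logit(yv, X).fit_regularized(alpha=1e-3, disp=False)
        return {"beta": float(ridge.params[foraging]), "se": float("nan"),
                "z": float("nan"), "p": float("nan"),
                "separation": True, "n": len(df)}


def validate_visits_vs_mass(records: pd.DataFrame, mass: str = "peak_mass",
                            visits: str = "august_visits", date: str = "peak_date",
                            burrow: str = "burrow", n_boot: int = 1000,
                            seed: int = 0) -> LMMResult:
    """Chick peak mass ~ colony visits + peak-mass date + (1 | burrow).

    The date fixed effect guards against later-measured chicks biasing the
    visits-mass relationship.  Raises when visits carry no variation.
    """
    df = records[[mass, visits, date, burrow]].dropna()
    if df[visits].nunique() < 2:
        raise ValueError("colony visits constant: slope inestimable")
    return fit_lmm(df, mass, [visits, date], burrow, focal=visits,
                   n_boot=n_boot, seed=seed)
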