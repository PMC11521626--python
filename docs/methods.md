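# Methods

This note records the models, rules and numerical choices behind each
stage, what the simulator does and does not emulate, and the limitations
a user should keep in mind.

## Solar geometry

All stages share one solar model (`shearlog.solar`): the NOAA
low-precision harmonic expansions for solar declination and the equation
of time (accuracy ~0.01°, minutes-level in time). Latitude is recovered
from day length by numerically inverting the sunrise equation
(`brentq`, tolerance 1e-4°): the scan brackets every root in (−89.5°,
89.5°), discards latitudes where the sun never crosses the horizon (no
real day/night cycle can generate a twilight there), and refuses with a
NaN when either (a) surviving roots more than 2° apart reproduce the
observed day length within 0.02 h — near an equinox with the calibration
angle close to −declination the day length is genuinely the same at
well-separated latitudes — or (b) the day length moves less than 0.002 h
across one degree of latitude around the root, the classic equinox
degeneracy. Refusals surface as invalid estimates with reason
`equinox-degenerate`; they are reported, never imputed.

## Light-level geolocation

Twilights are linear-interpolated crossings of a 10-unit threshold.
Shading produces spurious short dark spells (and nocturnal noise short
light spells); spells shorter than a 4 h refractory window are deleted
shortest-first, which protects a genuine twilight adjacent to a shading
blip. The window presumes real nights and days both exceed 4 h, true for
a boreal-breeding, austral-wintering migrant between ~40°S and ~62°N.

The sun elevation angle is calibrated per track over candidates
{−3, −3.5, −4, −4.5, −5}° by minimising the median absolute deviation of
June–July latitudes from the known colony latitude; ties break toward the
smaller |angle|. Daily positions get a centred 3-day rolling mean (min 1
valid member), with longitude averaged as a unit vector so the date line
and 0-meridian are safe. Monthly summaries first apply Tukey fences
(1.5×IQR, fence-inclusive — values exactly on a fence are retained) per
bird-month to each coordinate, require ≥ 5 surviving estimates, and mask
±15 days around equinoxes. The IQR fence multiplier and the per-bird-month
filtering scope are this package's choices; the fence-inclusive rule
mirrors the convention of retaining the bounds.

## Immersion behaviour

Scores are wet 3-s counts per 10-min bin, so 200 is saturation. At-sea
bins map 0 → flight, 200 → rest, 1–199 → foraging. Colony occupancy is
claimed only by two rules: a maximal daytime all-dry run ≥ 6 h (36 bins
fully inside sunrise–sunset) is a burrow stay, and a night whose
wet-event count falls in the drier component of a two-component Gaussian
mixture (posterior > 0.5) is a colony visit. The EM fit initialises means
at the 25th/75th percentiles, shared spread, equal weights; iterates to a
log-likelihood gain < 1e-8 (cap 1000); orders components so μ_dry < μ_sea;
and raises on degenerate input (all counts equal, or any component sd
collapsing below 1e-6). The mixture is fitted per bird by default
(`mixture_scope` also allows colony-year or pooled); the paper-scale
study pooled enough nights per bird (≥ 20) for this to be stable.
Incubation evidence is any all-dry run ≥ 3 days (432 bins); its absence
marks a bird-year as skipped breeding.

Foraging effort is 10/60 h per foraging bin in daylight, averaged per
day, divided by the day length at the bird's mean January position
(non-breeding) or at the colony (August). Proportions above 1 (night
foraging spillover) are flagged, never clipped. August colony visits
count distinct visit nights plus isolated daytime burrow stays whose
adjoining nights are not already visits (one continuous
night-day-night stay counts once per night); counting burrow days at all
is an interpretation choice, exposed as `include_burrow_days`.

## Phenology

Migration dates come from longitude displacement relative to the colony:
a qualifying run is ≥ K = 5 consecutive days displaced > D = 10° toward
the non-breeding side. The reported southbound start is the last day
within 1° of the colony longitude on the monotone departure limb before
the first qualifying run (i.e. the departure day), northbound start the
last day on the winter-longitude plateau before the sustained return, and
northbound end the first day back within 1° of the colony. K, D and the
1° home band are configuration; the defaults were validated by exact
(±1 day) recovery on clean simulated tracks. Where the original workflow
used visual inspection, this rule is the reproducible surrogate.

## Environmental covariates

Seasonal index means: October–December for the ENSO-like index (the
non-breeding covariate), December–March for winter NAO (December assigned
to the following year's winter) and June–August for summer NAO; a missing
month makes the season missing with a reason. The chlorophyll-peak
latitude is the argmax over latitude rows of the zonal (missing-aware)
mean within the 35–45°S, 59–63°W box; ties go to the latitude nearest the
box centre. A `max-cell` alternative exists; zonal mean is the default
because a single-pixel bloom should not move the peak.

## Inference

The path model is a recursive linear system over observed bird-year
variables (default standardised). For such systems the ML solution
coincides with equation-wise least squares, which is how it is computed;
standard errors come from the information matrix (ML residual variance).
The model-implied covariance (I − B)⁻¹ Ψ (I − B)⁻ᵀ — with endogenous
error variances scaled to the ddof-1 sample covariance so a saturated
model fits exactly — gives χ² = (n−1)·F_ML and the usual indices: CFI and
TLI against the independence baseline (clipped to [0, 1]), RMSEA =
√(max(χ²−df, 0)/(df·(n−1))) and SRMR over the standardised lower
triangle. Multiple testing uses α = 0.05 / k^(1−r̄), with r̄ the mean
absolute pairwise correlation among the modelled variables, supplied by
the caller because it depends on the data at hand.

The random-intercept mixed model profiles the deviance over the variance
ratio λ = τ²/σ² (bounded ≥ 0, scalar optimisation to 1e-8; the closed-form
GLS per λ uses group-wise downdates, so a fit costs ~1 ms and bootstrap
refits are cheap). λ below 1e-5 is reported as the zero boundary with a
singular-fit warning. Inference is by likelihood-ratio tests on ML fits
(χ², 1 df) and parametric-bootstrap percentile intervals (default 1000
draws, seeded; coverage-style test loops use fewer draws per replicate —
at least 150 — with at least 150–200 replicates). Subject centring fits
y ~ x̄_j + (x−x̄_j) + (1|bird); the difference test refits in the
(x, x̄_j) parametrisation, where the x̄_j coefficient equals
between − within. Note the between effect is defined on the *observed*
per-bird mean; simulations that apply a between slope to a latent mean
will see the usual attenuation, which is a property of the method, not a
bug. The skipped-breeding model is a logit GLM; complete separation is
flagged and a small-ridge penalised estimate reported in its place. The
chick-mass validation is mass ~ visits + peak-date + (1|burrow).

## The simulator

Defaults describe the study conditions: a Skomer-like colony (51.74°N,
5.29°W), winter base 42°S/58°W on the Patagonian shelf, within-individual
slope −0.30° latitude per index unit over bird-level spread (sd 1.5°) and
year noise (sd 0.5°); phenology means at day-of-year 255 (southbound
start), 60 (northbound start) and 85 (return) with sds 7/7/5 and the
northbound leg clamped to ≥ 10 days so no day jumps > 1500 km; a
standardised AR(1) monthly index (coefficient 0.5, innovation sd 1);
staggered contiguous 2–4-year deployments per bird, mirroring rotating
logger redeployment (and giving the between-bird covariate its
variation); light every 5 min as a logistic function of solar elevation
crossing 10 units at −4° elevation, clipped at 64, with 5% shading;
behaviour as a first-order Markov chain over flight/forage/rest with
separate day/night matrices, 30% night-visit probability while resident,
one 5-day incubation stint in June; and a chlorophyll ridge whose peak
sits at −40° + (−2.4°)·index + noise (the bloom shifts north under the
negative index phase, as the birds do). Every bird-year draws from an
independent stream keyed by (seed, bird, year), so any piece can be
regenerated alone, bit-identically.

What the simulator does **not** emulate: weather- and sensor-dependent
shading structure (shading is i.i.d.), clock drift, logger failure,
sea-surface temperature, winds, real prey fields, geographic barriers on
migration (tracks interpolate linearly), or density dependence. Passing
tests therefore demonstrate the pipeline's internal correctness and its
recovery of programmed effects under realistic signal-to-noise — not
field accuracy against ground-truthed GPS, which published validations of
these methods address.

## Problem sizes

The default test suite and the acceptance script run the study at reduced
but representative sizes — 50 bird-years for the geolocation round trip,
300–500 random triples for the latitude inversion, 400 nights for the
mixture, 200 replicates for path-model coverage and the centring
difference test, and a 10-bird × 4-year end-to-end run — chosen as the
package's own verification budget; all scale up by configuration.

## Known limitations

* Threshold geolocation is undefined near equinoxes; the pipeline masks
  ±15 days rather than modelling through them (no template fits or
  state-space smoothing, by design).
* Phenology detection presumes a single out-and-back cycle per
  bird-year; double migrations or mid-winter relocations > 10° would
  confuse the plateau logic.
* The path model handles observed variables only (no latent factors, no
  non-recursive loops) and missingness by complete cases per model.
* Mixed models support a single random intercept; crossed or nested
  random effects are out of scope.
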