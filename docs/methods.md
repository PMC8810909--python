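# Methods

## Model

The response is a binary melanism indicator per squirrel observation
(1 = melanic; gray and the rare "other" morphs = 0).  The model is a
binomial GLMM with logit link:

```
logit P(y_ij = 1) = x_ij' β + u_j,   u_j ~ N(0, σ²_city)
```

for observation *i* in city *j*.  Fixed effects: within-city
urbanization (impervious cover), winter temperature (mean temperature
of the coldest quarter, °C), forest cover (%), log city area (ha), and
the two-way interaction of each city-level covariate with impervious
cover.  Because the absolute range of impervious cover differs between
metropolises and small towns, impervious cover is min–max rescaled to
[0, 1] *within* each city before modelling, so its slope is the
urban-to-rural contrast on a common scale in every city.  All
predictors are then standardized (mean 0, SD 1) over the analysis
frame; interaction columns are products of standardized mains.  The
standardization statistics are stored with the fit and re-applied at
prediction time, so cline curves can be requested in raw units
(°C, %, ha).

Assumptions: a single random intercept captures among-city
heterogeneity (no random slopes); observations are conditionally
independent given the city effect and covariates — the residual
autocovariate below is the guard against violations of that
independence in space.

## Estimation

The marginal likelihood integrates over the city intercepts; with one
scalar intercept per city the integral factorizes and each factor is
handled by a Laplace approximation.  Fitting is two-stage:

1. **Starting values** — a penalized IRLS that jointly profiles
   (β, u) at fixed σ (each solve is a Schur-complement system in the
   fixed-effect block, O(n·p²)), inside a bounded scalar search over
   log σ.  Step-halving keeps the penalized log-likelihood monotone —
   without it IRLS can run away on a few percent of survey-scale
   replicates.  This stage is fast but returns slightly attenuated β,
   because it puts β at the joint penalized mode rather than at the
   optimum of the Laplace objective.
2. **Polish** — quasi-Newton (L-BFGS-B) over (β, log σ) on the full
   Laplace objective, with only the conditional modes u profiled by an
   inner vectorized Newton solve (tolerance 1e−11 on the step).
   Relative objective tolerance 1e−12, gradient tolerance 1e−6,
   200 outer iterations, log σ bounded in [−8, 3].

σ is parameterized on the log scale to keep positivity; an estimate
collapsing to the lower bound raises a boundary warning and flags the
fit.  Standard errors for β come from the fixed-effect block of the
inverse penalized information at the optimum, conditional on σ̂ — the
usual Wald machinery for this model class, and the basis of the
two-sided Wald tests.  On a 2,000-row fixture the whole procedure
agrees with `lme4::glmer` (Laplace) to ≲ 5e−3 on coefficients, 2% on
SEs, 5e−3 on σ̂ and 0.05 on the log-likelihood (see
`tests/test_glmm.py`); with σ pinned at 0 it reproduces plain logistic
IRLS to 1e−6.

The Laplace approximation is least accurate for cities with few
observations and extreme prevalence; at the survey's city sizes
(≥ 101) this is immaterial, but fits to much smaller clusters should
be read with that caveat.  A second caveat is interval calibration:
because the Wald SEs condition on σ̂, intervals for *city-level*
covariates (informed by only 43 cities) run slightly narrow — in the
100-replicate recovery study their empirical coverage sits around
0.89–0.95 against the nominal 0.95, while observation-level terms are
nominal.  This is shared with the reference mixed-model machinery,
not specific to this implementation.

## Spatial correction

Residual autocovariate (RAC): response-scale residuals (y − p̂, with
p̂ conditional on the fitted city effects) are taken from the initial
fit; symmetric inverse-distance weights w = 1/d ("B" style, no row
standardization) connect all point pairs within a radius, defaulting
to the greatest nearest-neighbour distance of the data; each point's
autocovariate is the weighted mean of its neighbours' residuals
(isolated points get 0); the autocovariate is standardized like every
other predictor and the model is refit with it included.  A
configuration switch selects Pearson residuals instead; response
residuals are the default because they match the cited
residuals-autocovariate workflow.  Coincident points (possible even
after 10-m thinning once geographic coordinates are projected) get a
distance floor of half the minimum nonzero pairwise distance.
Correlograms report Moran's I in 1-km rings from 0 to the radius,
with binary within-bin weights; the permutation expectation
−1/(n−1) and the 2×2 checkerboard value −1 are test oracles.

Known limitation: because the autocovariate is built from the model's
own residuals, its coefficient has a mild negative bias under the
null (fitted residuals are sum-constrained within cities), and the
refit slightly absorbs genuine fixed-effect signal when spatial noise
is strong.  The tests assert what holds empirically: near-zero null
coefficients, and first-bin Moran's I reduced below 0.05 when the
simulated noise field is present.

## Geometry

All metric work is planar, in meters.  Geographic inputs are projected
per city with a spherical azimuthal equidistant projection centred on
the city centroid — exact in distance from the centre, and accurate to
well below 1% at the tens-of-kilometres scale of one study region.
Cardinal-extent distances for buffering are measured from the
footprint centroid to the bounding-box edges (the "maximum extent"
reading adopted where the alternative — farthest vertex per axis —
was equally defensible); the buffer is 25% of their mean.  Rasters are
planar square-cell grids serialized as ESRI ASCII text.  Disc
extraction uses per-cell circle/cell intersection areas (Gauss–
Legendre, exact for interior cells); for large observation tables a
kernel path applies the same weights centred on each point's cell,
which differs from the exact value only by a sub-cell window shift
(verified < 1% on smooth fields).  Polygon extraction takes full cell
areas for interior cells and exact shapely intersections for boundary
cells.

Spatial thinning solves each connected component of the conflict graph
(pairs closer than the minimum distance): components of ≤ 28 points
are solved to a true maximum independent set by branch and bound;
larger components use seeded greedy removal of the most-conflicted
point over replicates, keeping the best replicate.  Exact small-
component solutions both retain more records and make the brute-force
oracle comparison an equality rather than a heuristic bound.

Open choices resolved as defaults (each with a switch or documented
rule): "unclear" votes count in the agreement denominator; color votes
in multi-squirrel images pair by slot index; impervious cover is
rescaled then standardized (`standardize_rescaled=False` uses the raw
percent); overlapping retained cities compare sample size first and
convex-hull spread only within a 5% sample-size tie; observations in
more than one surviving region go to the nearer centroid; a city with
constant impervious cover rescales to 0 with a warning (it contributes
no within-city cline information); weights are one global object, so
the auto radius is computed on the assembled multi-city frame.

## Synthetic generator

The generator's defaults emulate the survey that motivated the
pipeline:

| parameter | default | why |
|---|---|---|
| cities | 43 | survey size |
| per-city counts | lognormal, median 254, clipped to [101, 4731], rescaled to a 26,924 total | the survey's count distribution |
| city area | log-uniform 25,000–350,000 ha | the survey's small/large contrast |
| winter temperature | uniform −11 to 9 °C | spans the cold/warm contrast (−5/5 °C) |
| forest cover | uniform 10–50% | spans the low/high contrast (15/45%) |
| β (standardized) | (−2.3, 0.17, −2.14, 0.25, 0.58, −0.30, 0.15, 0.13) | reported main/interaction effects; intercept, forest main and imperv×temp are this package's realistic choices (overall melanism near 12%, steeper clines in colder cities) |
| σ_city | 1.5 | makes city-level coefficient SEs comparable to the reported 0.28–0.33 |
| raster cell | 150 m | smooth at the 1-km extraction radius; keeps 50-replicate studies in minutes |
| observer effort k | 2 | point density ∝ 1 + k·imperv/100 — urban bias with nonzero rural mass |
| vote error | 0.02, 10 voters | consensus accuracy near the survey's reported ~99.8% |
| spatial noise | exponential covariance, range 5 km; SD 1.5 in the RAC study | SD calibrated so the uncorrected first-bin residual Moran's I is ≈ 0.11 |

Impervious cover decays logistically with distance from the city
centroid (midpoint at 0.9 of the equal-area radius, steepness a third
of it) plus amplitude-scaled white noise, clipped to [0, 100]; the
spatial noise field is simulated on a coarse grid (half the range) and
bilinearly interpolated.  Melanism is drawn from the exact model the
fitting stage assumes, with covariates transformed by the same code
path (within-city rescale, then standardize).

What the generator does **not** emulate: real impervious/forest
geometry (rings, rivers, satellite towns), temporally varying effort,
observer misidentification that correlates with habitat, spatially
structured vote error, or imperfect city footprints.  Passing recovery
tests therefore demonstrate that the *pipeline* is correct and well
calibrated under the survey's statistical structure — not that any
particular real dataset satisfies that structure.

## Study scales

Replicate studies are sized to run on one CPU in minutes:

* **Recovery study** — 50 replicates at full survey scale (43 cities,
  26,924 observations each).  Each estimate is checked against its
  generative value within twice the reported SE; 95% Wald intervals
  are checked for 0.90–0.99 empirical coverage.
* **RAC study** — 50 replicates at a reduced scale chosen for the
  spatial computations: 12 cities of 5,000–60,000 ha, ~4,000
  observations, noise as above.  Reported: the maximum distance-binned
  Moran's I of corrected residuals (median across replicates), with
  the uncorrected first-bin value verified to sit near 0.11.
* The GLM-limit, Moran, thinning and consensus oracles run at small
  fixed sizes (2,000 rows; n = 100 with 1,000 permutations; 100
  fixtures of ≤ 15 points; 10,000 vote records).

## Diagnostics

Binned residual plots: rows sorted by fitted probability (stable sort,
then row index), cut into ⌈√n⌉ equal-count bins by default, each bin
reporting the mean residual and a ±2·sd/√n band.  On correctly
specified *fixed-effect* simulations ≥ 93% of bins fall inside the
band (200-replicate check).  For conditional GLMM fits the band is
anti-conservative — within-bin residuals share city-intercept
estimation error — so in-band fractions below the nominal 95% on a
single mixed fit indicate shrinkage noise, not necessarily misfit.

Sensitivity analysis refits the model over thinning distances
{10, 50, 100} m × impervious radii {500 m, 1 km, 10 km}; on simulated
data the urbanization coefficient moves by well under 10% across the
grid, mirroring the robustness expected of the design.
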