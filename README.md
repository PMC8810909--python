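# urbancline

Urban–rural cline analysis of coat-color melanism in eastern gray
squirrels (*Sciurus carolinensis*), built as a tested, fully synthetic-
verifiable pipeline.  The package covers every stage of a multi-city
community-science survey:

1. **Vote consensus** — crowdsourced image classifications (number of
   squirrels, coat color of each) are aggregated with an 80% agreement
   threshold; "unclear" votes count against agreement but never become
   observations; two-morph images yield two records.
2. **Geographic preparation** — city footprints are buffered by 25% of
   the mean centroid-to-extent distance in the four cardinal
   directions; observations are spatially thinned to a 10-m minimum
   distance; cities need ≥ 100 observations and overlapping cities are
   de-overlapped by sample size then spatial spread; percent
   impervious cover is extracted as an area-weighted mean within 1 km
   of each observation.
3. **Model fitting** — a binomial GLMM on the logit scale:

   ```
   logit P(melanic_ij = 1) = β0 + β1·imperv_ij + β2·temp_j + β3·forest_j + β4·log(area_j)
                            + β5·imperv·temp + β6·imperv·forest + β7·imperv·log(area)
                            + u_j,     u_j ~ N(0, σ²_city)
   ```

   with impervious cover min–max rescaled to [0, 1] within each city,
   all predictors standardized (mean 0, SD 1), a Laplace-approximated
   marginal likelihood, and two-sided Wald tests.
4. **Spatial correction** — a residual autocovariate: symmetric
   inverse-distance ("B"-style) weights within a radius equal to the
   greatest nearest-neighbour distance, each point's weighted mean of
   neighbouring residuals standardized and added as a predictor, with
   Moran's I correlograms before and after.
5. **Synthetic data** — a generator that emulates the full survey (43
   cities, long-tailed per-city counts totalling ~27k, logistic
   impervious decay from each city core, urban observer-effort bias,
   optional spatially autocorrelated logit-scale noise, noisy crowd
   votes), so that every stage is verifiable by parameter recovery
   without downloading anything.

Who it is for: quantitative ecologists studying phenotypic clines
along urbanization gradients, and anyone needing a self-contained
reference implementation of the consensus → thinning → GLMM → residual
autocovariate workflow.

## Worked example

```python
import numpy as np
from urbancline import SimConfig, simulate_frame, fit_glmm, wald_tests, rac_refit

cfg = SimConfig(seed=7)          # 43 cities, ~27k observations
frame, landscapes, obs, u = simulate_frame(cfg)
fit = fit_glmm(frame)
print(wald_tests(fit).round(3))
```

prints (seed 7):

```
                 term  estimate     se      z      p
0           intercept    -2.487  0.251 -9.906  0.000
1            x_imperv     0.175  0.033  5.319  0.000
2              x_temp    -2.039  0.258 -7.912  0.000
3            x_forest     0.043  0.230  0.185  0.853
4           x_logsize     0.843  0.253  3.339  0.001
5     x_imperv:x_temp    -0.328  0.041 -8.025  0.000
6   x_imperv:x_forest     0.156  0.031  5.026  0.000
7  x_imperv:x_logsize     0.131  0.027  4.834  0.000
```

The generative values were (−2.3, 0.17, −2.14, 0.25, 0.58, −0.30,
0.15, 0.13): melanism rises with urbanization (positive `x_imperv`),
falls steeply with warmer winters (`x_temp`), and the urbanization
cline steepens in larger, more forested, colder cities (the
interaction terms).  Every estimate sits within two standard errors of
its generative value.

## Analysis drivers

`analysis/` holds numbered narrative scripts that run each stage on a
deterministic mid-sized synthetic survey and write tables under
`results/analysis/` (row-level tables under `scratch/`):

```
python analysis/01_simulate_study.py   # landscapes, observations, votes
python analysis/02_consensus.py        # 80% agreement aggregation
python analysis/03_geoprep.py          # thin, buffer, select, build frame
python analysis/04_fit_model.py        # GLMM, Wald tests, cline curves
python analysis/05_spatial_rac.py      # autocovariate correction
python analysis/06_sensitivity.py      # thinning x buffer-radius grid
```

## Using real data

The pipeline consumes observation tables (CSV), city footprints
(GeoJSON, planar meters or lon/lat — geographic coordinates are
projected per city with a local azimuthal equidistant projection), and
covariate rasters (ESRI ASCII grid via `urbancline.raster.Raster`).
An adapter for the survey's deposited observation dataset only needs
to map its columns onto the `Observation` schema
(`obs_id, x, y, color`); none of the tests require it.
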