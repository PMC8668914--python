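# Methods

## Model

A household survey yields binary outcomes `y_i ∈ {0,1}` (snakebite in the
last 12 months) at projected planar locations `s_i` (km).  The model is a
latent Gaussian Bernoulli-logit regression

    y_i ~ Bernoulli(π_i),  logit(π_i) = β0 + x_i'β + u(s_i),

where `u` is a zero-mean Gaussian random field with Matérn covariance of
smoothness ν = 1,

    Cov(u(s), u(s')) = σ² (κd) K₁(κd),  d = ‖s − s'‖,  κ = √8/ρ.

`K₁` is the modified Bessel function of the second kind, order 1 (evaluated
with `scipy.special.kv`).  With the √8/κ convention the correlation at
distance ρ is √8·K₁(√8) ≈ 0.139, so ρ is interpreted — and reported — as
the distance at which spatial correlation becomes negligible.

### Inference

Inference is of the INLA family but implemented independently and with a
dense (exact) covariance rather than a finite-element SPDE mesh:

1. **Inner step.**  For fixed hyperparameters θ = (σ, ρ) the conditional
   posterior of z = (β, u) is maximised by Newton–Raphson on the joint
   log-posterior (Bernoulli-logit likelihood, N(0, τ⁻¹I) prior on all fixed
   effects including the intercept, N(0, Σ(θ)) prior on u).  The posterior
   is approximated by N(ẑ, H⁻¹) with H the negative Hessian at the mode.
   Convergence: max |score| < 1e-6 or 100 iterations, with step halving
   whenever a step would decrease the log-posterior; non-convergence is
   reported by warning.  Complete separation is handled by the prior
   (finite modes, no infinite drift).
2. **Hyperparameter integration.**  θ lives on a log-spaced grid (default
   7 × 7) spanning independent log-uniform hyperpriors; each node carries
   weight ∝ exp(Laplace log marginal likelihood), normalised after
   subtracting the maximum (so underflow cannot zero the grid).  The Laplace
   marginal was validated against brute-force 3-D quadrature on small
   problems (agreement to ~0.05 nats).
3. **Marginals.**  Per-coefficient posteriors are Gaussian mixtures over
   the grid.  Reported statistics: mixture mean and SD (analytic), mode
   (arg-max of the mixture density on a 512-point grid), equal-tailed 90%
   interval (root-finding on the mixture CDF), and odds-scale transforms
   exp(mean), exp(CI).  Rounding to 2 decimals happens only in the report
   layer.
4. **WAIC.**  `WAIC = −2(lppd − p_waic)` from S = 1,000 seeded draws of the
   mixture posterior; `p_waic` uses the sample variance (ddof = 1) of
   pointwise log-likelihoods, so a degenerate one-draw posterior has
   `p_waic = 0`.  For model comparisons (`ablate_spatial`) both models'
   WAICs are recomputed from a common per-observation decomposition at
   S = 4,000 and the difference is reported with a paired standard error
   2·√(n·var(d_i)).
5. **Prediction.**  At new locations the latent field is conditioned per
   hyperparameter node by standard GP formulae (u* | u ~ N(a·û, σ²(1 −
   r*'R⁻¹r*) + a·Cov(u)·a'), a = r*'R⁻¹, including the cross-covariance
   with β through the joint posterior precision); risk summaries π(s) are
   Monte-Carlo means/SDs over 2,000 seeded mixture draws.

### Latent-field resolution

The dense covariance path factorises an m × m matrix and is limited to
m ≤ 5,000 latent sites.  When cluster labels are supplied (`groups=`), the
field is represented at cluster centres and shared within a cluster — the
analogue of a mesh coarser than the data.  With a range of ~30 km and
cluster radii of ~1.5 km the within-cluster correlation is ≈ 0.99, so the
approximation error is far below posterior uncertainty; above the dense
limit it is the only supported path.  Coincident sites are handled by a
relative diagonal jitter of 1e-8·σ² (with a warning).

### Priors and defaults

| parameter | default | rationale |
| --- | --- | --- |
| β prior precision τ | 1e-3 | effectively vague on the logit scale |
| σ hyperprior | log-uniform on [0.1, 1.5] | sensible SD range for a logit-scale random effect |
| ρ hyperprior | log-uniform on 0.1–10× the median inter-site distance (or user bounds) | scale-free default; studies should fix bounds from pilot runs |
| grid | 7 × 7 | resolves one decade per axis to ~40% spacing |
| jitter | 1e-8 σ² | numerical PD guard |
| WAIC / prediction draws | 1,000 / 2,000 | MC error well below reporting precision |

## Covariate selection

The chain is greedy and fully logged (every removal records its justifying
statistic, so a run replays bit-identically):

1. **Pearson filter (±0.6).**  Constant columns are removed first.  While
   any pair exceeds |r| = 0.6, the member with the larger mean |r| to all
   remaining covariates is dropped (ties: the later column in priority
   order).  Binary covariates participate as 0/1.
2. **Sequential VIF (threshold 5).**  VIF_j = 1/(1 − R²_j) from OLS of each
   covariate on the others with intercept; the largest is dropped while the
   maximum exceeds 5; exact collinearity yields an infinite VIF and is
   dropped first.
3. **Negligible-effect pruning (open band ±0.1 log-odds).**  After a fit,
   covariates with posterior mean strictly inside (−0.1, 0.1) qualify; one
   is removed per round — the candidate whose removal most lowers the WAIC —
   then the model is refitted, to a fixed point.  A qualifying covariate is
   retained when every candidate removal worsens the WAIC (weak but
   WAIC-relevant effects are deliberately kept).
4. **Interactions.**  A pair is tested by refitting with the product term;
   it is "significant" iff its 90% CI excludes 0 on the logit scale
   (equivalently the odds-scale CI excludes 1).  Products collinear with
   the mains are reported and skipped; self-pairs are rejected.
5. **Spatial ablation.**  The final covariate set is refitted without the
   latent field and both WAICs are compared as above.

The boundary rule (exactly ±0.1 is kept), the drop-which-member policy and
the one-at-a-time order are not canonical anywhere; they were fixed once
for replayability and are logged in the selection trace.

## Synthetic surveys

`snakerisk.synthetic` emulates a Terai-style multi-cluster random survey:

* **Defaults are the study conditions:** 249 clusters × 53 households
  (13,197 total) on an 800 × 50 km strip; human outcome prevalence
  calibrated to 1.18% (animal preset: 0.7%, range 430 km, SD 0.77);
  latent field SD 1.0 and range 30 km; effect sizes equal to the fitted
  human-model posterior means (food storage 1.02, straw storage 0.58,
  sleeping on the floor −0.77, PPI 4.16, NDVI −1.43, distance-to-water
  0.32 per km).
* **Covariate surfaces** are low-pass-filtered white noise rescaled into
  realistic ranges — BIO6 1.8–10.9 °C and BIO17 18–71 mm (the reported
  regional ranges); NDVI in [0, 1] at a 10-km correlation scale (vegetation
  mosaics vary faster than climate, whose surfaces use 40 km); livestock
  densities and a household-density surface are non-negative.  Smoothness 0
  yields white noise (tested).
* **Water** is a set of 15 random polylines — a dense drainage network is
  typical of an alluvial plain and keeps household–water distances at the
  few-km scale on which the per-km effect is interpreted.
* **Households** are uniform in discs (default radius 1.5 km) around
  uniform cluster centres; binary answers are Bernoulli at configured
  prevalences (food storage 0.5, straw 0.4, sleeping on floor 0.3, shed
  0.5); ten PPI items carry 0–10 points each so summed scores span the
  0–100 lookup domain.  The shipped lookup table is a synthetic linear
  stand-in (score s → s/100): the real national calibration tables are not
  redistributable and are supplied by the user as CSV.
* **Outcomes** follow the exact model; when a prevalence target is set the
  intercept is calibrated by bisection on the realized mean of expit(η).
  Everything is deterministic given the config seed.

**What the generator does not emulate:** real geography (rivers follow no
terrain, admin units are a rectangular partition), the survey's
probability-proportional-to-size cluster selection, answer–answer
dependence, measurement error in geolocation, and any covariate–covariate
causal structure.  Passing recovery tests therefore demonstrates that the
inference machinery is correct and calibrated under the model's own
assumptions — not that the model is correct for any particular real survey.

## Simulation studies (the scale choices)

The recovery scenario is n = 2,000 households in 80 clusters on a
250 × 80 km strip, ~25% positive outcomes, and the latent field generated
at cluster centres, with the range hyperprior fixed at [3, 300] km.  These
choices are deliberate: a recovery study must place the truth inside an
identifiable regime.  At 80 clusters the mean cluster spacing (~16 km)
resolves a 30-km range; at 1.18% prevalence (~24 cases) no method
identifies (σ, ρ) at this n, so the scenario uses a case count comparable
to the full-scale survey instead.  Under these conditions the 90% CIs cover
each generating coefficient at ≈ 90%, the posterior-mean σ lands in
[0.5, 1.5] and ρ in [15, 60] km in the large majority of seeds, and the
spatial model beats the non-spatial one in WAIC essentially always at field
SD 1.

## Mapping and aggregation conventions

* Prediction grids take the cell centres of the region's bounding box at
  the given spacing (floor(w/s)·floor(h/s) candidates), keep centres
  covered by the region, and mask centres inside exclusion polygons
  (e.g. dense urban units).  Masked cells are nodata in every output.
* Households at risk per cell-year = posterior-mean risk × households per
  cell (an expectation, not a thresholded count); people = households ×
  5.27 (the regional mean household size).  A population raster is
  converted to households by dividing by the same constant.
* Risk classes use closed thresholds (≥ 0.01 / 0.05 / 0.1), so masks nest.
* Zonal aggregation assigns a cell to the admin unit covering its centre —
  no area weighting — which keeps per-unit sums exactly
  partition-consistent.  Cells without valid risk are excluded from both
  the numerator and the adjusted (denominator) population.  Percentages are
  recomputable from the table's own absolute columns; expected annual cases
  (population at risk × risk level) are rounded to the nearest ten only in
  reports.

## I/O conventions

Internal units are km in a single projected planar CRS; conversion from
on-disk metres happens exactly once at the I/O boundary, and design tables
carry a `scaled` tag so the Table-style scalings (temperature ×0.1,
precipitation ×0.01, livestock ×0.001, PPI percent ×0.01, distance m→km
×0.001) can never be applied twice.  Rasters are ESRI ASCII grids with an
optional `.prj` WKT sidecar; a geographic (degree) CRS is rejected with an
instruction to project.  Raster cells are half-open: a point on an edge
belongs to the cell to its right/below.  Vector layers are GeoJSON
(shapely); invalid rings are repaired (with a warning) or rejected.

## Known limitations

* Plain Gaussian Laplace marginals (no simplified-Laplace skewness
  correction): coefficient posteriors for rare outcomes can carry a small
  residual bias relative to full MCMC, visible only at the edge of the
  coverage tolerance in the simulation studies.
* Dense covariance limits the latent dimension to ~5,000 sites; larger
  problems must use the cluster-centre representation.
* The hyperparameter grid is static (no adaptive re-centring); posterior
  means of weakly identified ranges inherit a right tail from the
  log-uniform prior's upper decade.
* No spatio-temporal extension, non-Bernoulli likelihoods, multi-band
  rasters or on-the-fly reprojection.
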