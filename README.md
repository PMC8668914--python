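# snakerisk

Model-based geostatistics for household snakebite-risk surveys: hierarchical
Bayesian logistic regression with a Matérn latent spatial field, INLA-style
Laplace-approximate inference, iterative covariate selection, kilometre-scale
risk mapping and population-at-risk aggregation by administrative unit.

## Who this is for

Spatial epidemiologists analysing clustered household surveys of a rare
binary outcome — here, whether anyone in a household suffered a snakebite in
the last 12 months — together with gridded environmental, climatic and
socio-economic covariates (NDVI, WorldClim bioclim surfaces, livestock
densities, a human-modification index, distance to permanent water, the
Poverty Probability Index).  The package also ships a first-class synthetic
survey generator so the entire pipeline is testable without any data
downloads, and supports parallel human and domestic-animal outcome models
(a One Health setting).

## The model

For household *i* at location *s<sub>i</sub>*:

```
SB(s_i) ~ Bernoulli(π(s_i))
logit(π(s_i)) = η(s_i) = β₀ + X(s_i)β + u(s_i)
u ~ GMRF(0, Σ),   Σ_ij = σ² (κ‖s_i − s_j‖) K₁(κ‖s_i − s_j‖),   κ = √8/ρ
```

with K₁ the modified Bessel function of the second kind of order 1 (Matérn,
ν = 1).  Under the √8/κ convention the range ρ is the distance at which
spatial correlation drops to ≈ 0.139 — effectively negligible.  Inference is
INLA-style: a Newton–Raphson Laplace approximation of the conditional
posterior of (β, u) at each node of a grid over (σ, ρ), nodes weighted by
the Laplace marginal likelihood under independent log-uniform hyperpriors
(σ in [0.1, 1.5] by default), and Gaussian-mixture posterior marginals.
Model comparison uses WAIC; covariate selection chains a ±0.6 Pearson
filter, sequential VIF (threshold 5), and iterative pruning of effects whose
posterior mean falls inside (−0.1, 0.1) on the log-odds scale.

The estimator follows scikit-learn conventions:

```python
SpatialLogisticGP(grid_size=7, sigma_bounds=(0.1, 1.5)).fit(X, y, coords=..., groups=...)
```

## Worked example

Simulate a survey at simulation-study scale (80 clusters × 25 households on
a 250 × 80 km strip, latent field SD 1 and range 30 km, fitted-model effect
sizes) and refit it:

```python
from snakerisk import SyntheticConfig, generate_survey, SpatialLogisticGP

cfg = SyntheticConfig(
    region_extent=(250.0, 80.0), n_clusters=80, households_per_cluster=25,
    outcome_prevalence_target=0.25, dense_limit=1, seed=1,
)
sv = generate_survey(cfg)
est = SpatialLogisticGP(rho_bounds=(3.0, 300.0), random_state=0).fit(
    sv.design[list(cfg.true_beta)],
    sv.households["outcome_human"].to_numpy(),
    coords=sv.coords,
    groups=sv.households["cluster_id"],
)
print(est.report_table())
print(f"rho: {est.rho_mean_:.2f} km   sigma: {est.sigma_mean_:.2f}   WAIC: {est.waic_:.2f}")
```

prints

```
               Mean    SD  Mode   Odds  Odds 90% CI LL  Odds 90% CI UL
coefficient
(Intercept)   -4.24  0.75 -4.22   0.01            0.00            0.05
food_storage   1.08  0.13  1.09   2.96            2.37            3.69
straw_storage  0.53  0.13  0.53   1.70            1.36            2.11
sleep_floor   -0.64  0.15 -0.64   0.53            0.41            0.67
ppi            3.50  0.66  3.50  33.17           11.23           97.96
ndvi          -1.10  1.03 -1.11   0.33            0.06            1.81
dist_water     0.26  0.03  0.26   1.30            1.23            1.37
rho: 34.17 km   sigma: 1.02   WAIC: 1598.40
```

Each `Odds` entry is exp(posterior mean): storing food multiplies the odds
of a household snakebite by ~3, each km of distance from permanent water by
~1.3, and moving across the full poverty-likelihood range by ~33; the fitted
range (34 km) and field SD (1.02) recover the generating values (30 km, 1).
The true coefficients used by the generator (e.g. food storage 1.02, PPI
4.16, NDVI −1.43) sit inside the 90% credible intervals.

The full pipeline is also scriptable from a shell:

```sh
snakerisk run --config config.yaml --seed 7
```

which chains simulate → prepare → select → fit → predict → aggregate →
report, writing the design matrix, selection trace, coefficient table, 1-km
risk mean/SD rasters, the households-at-risk surface, and the per-unit
population-at-risk table into the configured working directory.

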