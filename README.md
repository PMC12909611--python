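# seascapejsdm

Tools for asking how juvenile demersal fish — cod, haddock, whiting and
their neighbours — distribute themselves across a seascape of seabed
habitat patches, using baited-video counts and a hierarchical joint species
distribution model (JSDM).

The package covers the full analysis chain for a depth-stratified
stereo-baited-remote-underwater-video (SBRUV) survey:

- **Seascape covariates** from fuzzy substratum probability rasters: patch
  classification with per-class probability cutoffs (0.25 for hard-edged
  rock and cobble, 0.1 for soft sediments), distance to the nearest patch
  boundary, Shannon diversity of the surrounding substratum mosaic within
  500/1000/1500 m circles clipped to the study area, slope, aspect, depth
  stratum assignment and distance to shore.
- **Community assembly**: MaxN count matrices, a rarity filter (species
  seen in fewer than 10% of deployments per site-year are dropped) and
  species accumulation curves with their exact hypergeometric expectation.
- **The model**: a latent-factor Poisson JSDM fitted by MCMC, for
  deployment *i* and species *j*:

  ```
  y_ij ~ Poisson(lambda_ij)
  log lambda_ij = alpha_j + sum_k beta_kj x_ki + eps_S(i),j + eps_Y(i),j + u_i . v_j
  ```

  with N(0, 10^4) priors on intercepts and coefficients, Gamma(0.1, 0.1)
  priors on the site/year/loading precisions, latent deployment scores
  u_i ~ N(0, I) and species loadings v_j whose outer product V V' is the
  residual species covariance.
- **Evaluation**: WAIC with forward-backward stepwise term selection,
  diversity-radius selection, VIF collinearity screening, 5-fold
  cross-validated RMSE (also as % of each species' MaxN range), and
  variance partitioning across covariate groups and random terms.
- **Inference products**: a credible-interval-screened residual species
  association matrix (pairs whose 95% equal-tailed interval excludes zero),
  per-species prediction heat maps over the seascape, single-covariate
  response curves, and percent-of-area-present summaries.
- **Synthetic seascapes** with known ground truth — smooth bathymetry over
  the six design depth strata (0–116 m), six substratum classes with fuzzy
  (soft-sediment) and crisp (rock/cobble) boundaries, stratified deployment
  placement and counts drawn from the model above — so every stage is
  testable end to end without survey data.

Rasters are read and written as ESRI ASCII grids, tables as CSV,
configuration as YAML. A `seascapejsdm` CLI wraps the library for shell
use: `run-all` executes the full pipeline from a YAML config, `simulate`
writes just the synthetic seascape, and per-stage commands (`metrics`,
`filter`, `select`, `fit`, `diagnose`, `evaluate`, `associations`,
`predict`) stop after the named stage.

## Worked example

```python
import numpy as np
import seascapejsdm as sj
from seascapejsdm.synthetic import (
    SyntheticConfig, TrueParameters, default_cutoffs, simulate_counts,
)

# 1. synthetic seascape and survey (6 depth strata x 20 drops)
cfg = SyntheticConfig(seed=42)
bathy = sj.generate_bathymetry(cfg)
sub = sj.generate_substratum_probabilities(bathy, cfg)
deployments = sj.sample_deployments(bathy, cfg)

# 2. seascape covariates
patchmap = sj.classify_patches(sub, default_cutoffs())
features = sj.deployment_features(deployments, sub, patchmap, bathy)

# 3. counts from a known generative model (5 species, 1 latent factor)
spec = sj.ModelSpec.final_model(n_factors=1)
design = sj.build_design_matrix(features, spec)
rng = np.random.default_rng(0)
true = TrueParameters(
    species=["cod", "haddock", "whiting", "poor_cod", "plaice"],
    alpha=np.full(5, 0.8),
    beta=rng.normal(0, 0.3, size=(design.n_columns - 1, 5)),
    beta_columns=design.columns[1:],
    sigma_site=0.3, sigma_year=0.3,
    loadings=np.array([[0.9], [0.7], [-0.8], [0.3], [0.1]]),
)
sim = simulate_counts(design.matrix[:, 1:], true,
                      features["site"], features["year"], seed=1)
counts = sim.counts

# 4. fit the joint model
post = sj.sample_posterior(
    counts, design,
    settings=sj.MCMCSettings(chains=4, iterations=3000, burn_in=1000, seed=0),
    site=features["site"], year=features["year"], n_factors=1,
)
from seascapejsdm.diagnostics import summarize_convergence
conv = summarize_convergence(post)
print(f"max split R-hat = {conv['max_rhat']:.3f}, min ESS = {conv['min_ess']:.0f}")
print(f"WAIC = {sj.waic(post, counts):.1f}")

# 5. residual associations and a prediction map
R = sj.residual_correlation_draws(post.loading_draws())
assoc = sj.screen_associations(R, species=post.species)
print(assoc.screened().round(2))
pred = sj.predict_grid(post, patchmap, bathy, spec, conditioning={"year": 2022})
print(sj.percent_area_present(pred))
```

Output:

```
max split R-hat = 1.010, min ESS = 429
WAIC = 2281.5
           cod  haddock  whiting  poor_cod  plaice
cod       1.00     1.00    -1.00      0.99     NaN
haddock   1.00     1.00    -1.00      0.99     NaN
whiting  -1.00    -1.00     1.00     -0.99     NaN
poor_cod  0.99     0.99    -0.99      1.00     NaN
plaice     NaN      NaN      NaN       NaN     1.0
cod         96.2
haddock     74.2
whiting     93.5
poor_cod    80.3
plaice      82.7
```

Reading the output: the chains agree (R-hat near 1) and mix adequately
(smallest effective sample size 429 of 8000 retained draws).  The screened
association matrix shows which species pairs retain residual co-occurrence
signal after the covariates are accounted for — with a rank-1 latent
structure every defined residual correlation is ±1 by construction, the
screen decides which are supported, and plaice (generative loading near
zero) shows no supported association (blank/NaN cells).  The final block is
the percentage of the mapped seascape where each species' predicted
occurrence probability (1 − exp(−λ̂)) reaches 0.5, conditioned on survey
year 2022.

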