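# Methods

This note documents the statistical model, the sampler, the seascape
covariates, the synthetic-data generator, and the numerical and design
choices behind `seascapejsdm`.

## The model

For deployment *i* (one baited-video drop) and species *j*, the observed
MaxN count is modelled as

    y_ij ~ Poisson(lambda_ij)
    log lambda_ij = alpha_j + sum_k beta_kj x_ki
                    + eps_S(i),j + eps_Y(i),j + u_i . v_j

- **Fixed effects.** The covariate vector x_i holds reference-coded
  substratum class (C classes → C−1 columns), standardized continuous
  covariates (depth in metres positive downward, distance to the nearest
  patch boundary in metres, Shannon diversity of the surrounding
  substratum mosaic in nats at one radius), and interaction columns formed
  as products of coded columns.  The selected structure pairs substratum,
  depth, boundary distance and diversity with depth×substratum,
  boundary×substratum and depth×diversity — 20 columns with six classes.
  Priors: independent N(0, 10^4) on every intercept and coefficient.
- **Random intercepts.** eps_S and eps_Y are per-(site, species) and
  per-(year, species) normal intercepts with shared standard deviations
  sigma_S and sigma_Y per level type; the precisions carry Gamma(0.1, 0.1)
  priors.  The species-specific draws with a single shared SD mirror the
  level-wise variance components of hierarchical community models.
- **Latent factors.** Each deployment has a score vector u_i ~ N(0, I_F)
  and each species a loading vector v_j; their inner product absorbs
  residual co-variation among species (unmeasured environment or species
  interactions).  The loading elements share one precision with a
  Gamma(0.1, 0.1) prior.  Only Omega = V V′ — invariant to orthogonal
  rotation of the factors — is interpreted; U and V themselves are not
  identified and no rotational constraint is imposed.  Default F = 2,
  configurable ≥ 0.

## Sampling

The sampler is an adaptive Metropolis-within-Gibbs, numba-compiled, one
chain per kernel call:

- **Scalar random-walk updates** for every location parameter
  (coefficients, random intercepts, scores, loadings).  Each scalar block
  keeps its own log step size, adapted toward 44% acceptance by a
  Robbins–Monro rule during the first half of burn-in and frozen
  afterwards, so retained draws come from a fixed kernel.
- **Per-species Fisher preconditioning.**  Coefficients are sampled in the
  basis that orthonormalises the design under each species' approximate
  Poisson curvature, X′WX with weights w_ij = y_ij + ½ (plus the prior
  precision): theta_j = R_j^{-1} gamma_j with R_j the Cholesky factor.
  The normal prior is mapped exactly into that basis (a maintained
  prior-gradient vector makes the quadratic form O(p) per update).
  Componentwise walks in this basis mix well even for strongly informed
  species, where the raw coefficient posterior is sharp and correlated.
- **Exact translation (recentring) moves.**  Two families of
  likelihood-invariant translations have Gaussian full conditionals and
  are Gibbs-sampled each iteration: (i) transferring mass between a
  species' intercept and its site/year intercepts (only a handful of
  levels inform these, so intercept and random effects are separately
  weakly identified); (ii) for every factor f and design column x_k,
  shifting U[:, f] by c·x_k while moving theta_kj by −c·v_jf.  The second
  family removes the ridge along which latent scores mimic covariate
  effects, which otherwise dominates the autocorrelation time.
- **Conjugate precision draws** for the site, year and loading variance
  components (Gamma prior on the precision).  The Gamma-on-precision
  reading of the variance-component prior is the conjugate convention of
  the source framework; an inverse-gamma-on-variance parameterisation is
  the same distribution family and is noted here for clarity.
- **Seeds.** One master seed expands into per-chain seeds via
  `SeedSequence(seed, spawn_key=(chain,))`; all seeds stay below 2^31.
  Identical settings and seed reproduce draws bit for bit.
- **Prior-only mode** samples every block directly from its prior
  (likelihood disabled); it is used to verify the N(0, 10^4) coefficient
  prior (sample SD ≈ 100).

A per-cell lognormal-residual augmentation (making the coefficient updates
conjugate) was considered and rejected: when the generative counts are
pure Poisson the auxiliary residual variance collapses toward zero and the
conditional updates freeze, which defeats parameter-recovery testing.  The
all-Metropolis scheme with exact recentring reaches split-R̂ ≈ 1.01–1.04 on
the default synthetic problems at 4 chains × 3000 iterations.

The published schedule this emulates is 8 chains × 30,000 iterations with
10,000 transient and thinning 10 (2000 retained per chain, 16,000 total);
`mcmc_schedule` reproduces that arithmetic.  Desk-scale runs here use
4 × 3000 (tests and acceptance script) and 2 × 1000–1500 for
model-selection search phases, with the winning structure intended to be
refit at the full schedule; these sizes are the package's defaults for its
own synthetic problems.

## Seascape covariates

- **Patch classification.**  A cell is labelled with every class whose
  probability meets its cutoff — 0.25 for hard-edged classes (rock, cobble
  boulder), 0.1 for soft sediments (mud, muddy sand, sand, gravel), which
  preserves the gradual ("fuzzy") transitions between soft classes.  The
  dominant class is the labelled class of highest probability.
- **Boundaries.**  A labelled cell is a boundary cell if an in-study
  4-neighbour has a different dominant class or no label, or if the cell
  itself carries ≥ 2 labels (overlap zone).  4-connectivity avoids
  spurious diagonal-only edges; multi-label cells make fuzzy transition
  zones register as boundary.  The shoreline is deliberately **not** a
  patch boundary — distance to shore is a separate covariate.
- **Distances** are planar Euclidean between cell centres, in projected
  metres; coordinates must be projected before use.
- **Shannon diversity** H = −Σ p_c ln p_c uses hard dominant-class
  proportions among in-study, labelled cells whose centres fall within the
  radius (cell-centre inclusion keeps the computation oracle-checkable);
  where the circle spills onto land or off the map only the in-area part
  counts.  Dominant-class (not probability-weighted) proportions reflect a
  classified map; radii 500/1000/1500 m bracket plausible daily juvenile
  gadoid movement, and radius selection picks the radius whose
  single-covariate model has the lowest WAIC (ties to the smallest).
- **Slope/aspect** come from Horn's 3×3 weighted finite differences on the
  depth surface (positive downward); aspect is the downslope compass
  direction and is NaN on flat cells.
- **Depth strata**: 0–9.9, 10–18.9, 19–29.9, 30–37.9, 38–49.9 and
  50–116 m, closed on the left; depths beyond 116 m are outside the
  design and rejected.

The moving-window (per-cell) versions used for prediction are the same
definitions computed by convolution (diversity) and exact Euclidean
distance transform (boundary/shore distance), so training and prediction
covariates share one scale; agreement with the per-deployment operations
is tested cell by cell.

## Community assembly

"Occurred in fewer than 10% of deployments at each site each year" is
implemented as: a species is common in a site-year group when its
occurrence count (deployments with MaxN > 0) reaches
ceiling(fraction × group size); ties at exactly the fraction are retained
(strict reading of "fewer than").  By default a species common in at least
one group is retained — a species common anywhere is modelled everywhere —
with an "all groups" mode available because the survey wording is
ambiguous; an absolute per-group occurrence threshold can replace the
fraction.  The species accumulation curve averages cumulative richness
over random permutations of deployment order and also returns the exact
hypergeometric expectation E[S_n] = Σ_j [1 − C(N−F_j, n)/C(N, n)] as an
internal oracle; the final gradient (species added by the last sample) is
the sampling-adequacy statistic.

## Evaluation

- **WAIC** = −2(lppd − p_WAIC), with lppd the summed log of draw-averaged
  cell densities and p_WAIC the summed across-draw variance of the cell
  log densities (sample variance, ddof 1; at least two draws required).
- **Stepwise selection** starts from the intercept-only model, alternating
  a best-single-addition and best-single-removal phase; any WAIC decrease
  (configurable minimum delta) is accepted; interactions are entertained
  only while both main effects are present, and dropping a main effect
  drops its interactions.  Fits are cached per structure and all use one
  short search schedule, so the search is deterministic given its seed.
- **VIF**_k = 1/(1−R²_k) from regressing column k (with intercept) on the
  remaining columns; exact collinearity reports infinity.  When two
  covariates are collinear the one whose single-covariate model has the
  worse WAIC is the natural drop (depth was preferred over shore distance
  in the source analysis).
- **Cross-validation**: deployments are randomly partitioned into k = 5
  seeded folds; the held-out prediction is the posterior mean of lambda
  with site/year intercepts at their sampled values (levels are shared
  across folds; a level missing from a training split predicts at zero
  effect with a warning) and the latent term at its zero-mean marginal.
  RMSE is computed per species over all held-out cells and also expressed
  as 100·RMSE/(MaxN range), to one decimal.
- **Variance partitioning**: per draw and species, the variance over
  deployments of each covariate group's partial predictor X_g beta_g plus
  the site, year and latent contributions, normalised to percentages
  summing to 100 and averaged over draws.

## Associations

Residual correlations are computed per draw from Omega = V V′ and screened
with equal-tailed 95% intervals: a pair is supported when both bounds
share a sign.  Equal-tailed (not HPD) intervals match the
"interval overlaps zero" screening criterion and are quantile-stable; at
least 40 draws are required for a 95% screen.  Draws where a species has
zero loading norm are dropped pairwise (count reported); a species with
zero loadings in every draw is excluded with a warning.  With one latent
factor all defined residual correlations are ±1 by construction — the
screen then only decides support — so two or more factors are needed for
graded correlation magnitudes.

## Prediction

Maps condition the random intercepts on chosen site/year levels and
marginalise the deployment-specific latent scores at zero; cells without a
dominant class, or whose class was unseen at training, are masked with a
count reported.  Response curves vary one covariate over its observed
range (extrapolation is an explicit opt-in) with the others at observed
means and substratum at the reference or a named class.  The
percent-area-present summary needs a presence rule, which no survey
defines: the default calls a cell present when the posterior-mean Poisson
occurrence probability 1 − exp(−lambda) reaches 0.5, the rule is
configurable, and every output records the rule used.

## Synthetic generator

The generator emulates the study system rather than any real map:

- **Bathymetry**: a shore strip on the western edge, an offshore-deepening
  ramp plus low-pass-filtered Gaussian noise, rescaled to the design range
  (default 0–116 m) so all six strata are populated.  Depth is stored
  positive downward everywhere.
- **Substratum probabilities**: each class gets a smooth random field
  (class-specific correlation length; soft sediments smoother) plus a
  depth-affinity bump (rock shallow through mud deep).  A class's
  probability is a logistic function of its score margin over the best
  competitor, with the logistic width ("fuzziness") wide for soft classes
  and narrow for hard ones — so the locally winning class sits near 1,
  losers near 0, and near-ties form transition zones whose width differs
  by class type, reproducing the fuzzy/crisp contrast.  Probabilities are
  per class in [0, 1] and intentionally do not sum to 1 across classes.
- **Survey**: equal numbers of deployments drawn without replacement from
  the eligible cells of each depth stratum (default 20 per stratum,
  n = 120; the larger test design uses 50, n = 300); two site labels
  (north/south bands) and survey years assigned at random, mirroring a
  two-site, multi-year survey.
- **Counts**: drawn from the model above with user-supplied true
  parameters; site/year effects and latent scores are redrawn per
  replicate, and the linear predictor is stored for oracle checks.
  Default magnitudes used in tests (alpha = 0.8, beta ~ N(0, 0.3²),
  sigma_S = sigma_Y = 0.3, loadings O(0.5–1)) give per-deployment counts
  of a few individuals with occasional large catches, the regime of MaxN
  data.
- **Seeds**: one master seed expands into independent substreams
  (bathymetry, substratum, deployments, counts) so stages can be
  regenerated independently; everything is bit-reproducible.
- The default cell size (25 m) is a free choice; the real product's
  resolution is not published.

What the generator does **not** emulate: observation error in MaxN (video
detectability, bait plume dynamics), spatially autocorrelated residuals
beyond the latent factor, temporal trends within a year, realistic
coastline geometry, or map-versus-video substratum disagreement (the
feature table carries the map-derived class; an observed-class column can
be supplied and selected in config).  Passing tests therefore demonstrate
the correctness and calibration of the pipeline under the stated model,
not robustness to these real-data complications.

## Numerical choices and degenerate inputs

- Cutoffs must lie in (0, 1); a missing class cutoff is an error.
- A location on a boundary cell has boundary distance exactly 0; a raster
  with no boundary cells raises rather than returning infinity.
- An empty diversity circle (no labelled in-study cell centre within the
  radius) raises; H is clamped only by arithmetic (it is 0 for one class
  and at most ln C).
- Split-R̂ is floored at 1 (the rank-normalised estimator can dip below 1
  by sampling noise) and returns exactly 1 for constant chains; ESS of a
  constant chain returns the total draw count with a warning.
- Non-divisible (iterations − burn-in)/thinning floors with a warning.
- WAIC with a single draw is an error (the variance term is undefined).
- Tied diversity radii resolve to the smallest radius.
- Counts must be nonnegative integers; file readers reject negatives,
  fractions and duplicate deployment ids at load time.

## Limitations

- The spatially structured (coordinate-based) random effect is a config
  stub that raises: the coordinate term was dropped during the source
  model selection, and this package does not implement Gaussian spatial
  covariance.
- No overdispersion term beyond the latent factor is included by default.
- The sampler is designed for desk-scale problems (tens of species,
  hundreds of deployments); very large surveys would warrant a blocked or
  gradient-based sampler.
- Equal-tailed screening controls the support decision only
  approximately; exact error calibration is not claimed.
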