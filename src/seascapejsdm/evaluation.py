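"""Model comparison and predictive evaluation.

WAIC drives structure selection (forward-backward stepwise over the
candidate term pool, and the choice among the 500/1000/1500 m diversity
radii); VIF screens collinear covariate pairs before selection; 5-fold
cross-validation with per-species RMSE — also expressed as a percentage of
each species' observed MaxN range — measures predictive power; and the
fitted model's explained variance is partitioned across covariate groups
and the random terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, ModelSpec, build_design_matrix
from .mcmc import (
    MCMCSettings,
    PosteriorSamples,
    PriorSpec,
    poisson_log_likelihood,
    sample_posterior,
)

#: reduced schedule used while searching over structures; the winning
#: structure is refit at the full schedule
SEARCH_SETTINGS = MCMCSettings(chains=2, iterations=1500, burn_in=500, thinning=1)


def fit_model(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = MCMCSettings(),
) -> PosteriorSamples:
    """Build the design for ``spec`` and sample the posterior."""
    design = build_design_matrix(features, spec)
    return sample_posterior(
        counts,
        design,
        priors,
        settings,
        site=features["site"] if spec.use_site else None,
        year=features["year"] if spec.use_year else None,
        n_factors=spec.n_factors,
    )


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------


def waic_from_cell_loglik(logp: np.ndarray) -> tuple[float, float, float]:
    """(waic, lppd, p_waic) from per-draw, per-cell log densities.

    lppd sums log of the draw-averaged density; the effective-parameter
    penalty sums the across-draw variance of the log density.
    """
    logp = np.asarray(logp, dtype=float)
    if logp.shape[0] < 2:
        raise ValueError("WAIC variance term needs at least two draws")
    m = logp.max(axis=0)
    lppd = float((m + np.log(np.mean(np.exp(logp - m), axis=0))).sum())
    p_waic = float(logp.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic), lppd, p_waic


def waic(posterior: PosteriorSamples, counts: pd.DataFrame) -> float:
    """Widely applicable information criterion of a fitted model."""
    eta = posterior.fitted_linear_predictor(include_latent=True)
    y = counts.to_numpy(dtype=float)
    logp = poisson_log_likelihood(y[None, :, :], np.exp(eta))
    value, _, _ = waic_from_cell_loglik(logp.reshape(logp.shape[0], -1))
    return value


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------


def vif(design: DesignMatrix | np.ndarray) -> pd.Series:
    """Variance inflation factor per non-intercept column.

    VIF_k = 1 / (1 - R^2) of column k regressed (with intercept) on the
    other columns; exact collinearity reports infinity.
    """
    if isinstance(design, DesignMatrix):
        X = design.matrix[:, 1:]
        names = design.columns[1:]
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{k}" for k in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two non-intercept columns")
    out = {}
    ones = np.ones((X.shape[0], 1))
    for k, name in enumerate(names):
        yk = X[:, k]
        others = np.hstack([ones, np.delete(X, k, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ coef
        sst = ((yk - yk.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

Term = str
Move = tuple[str, object, float, bool]  # action, term, waic, accepted


@dataclass
class SelectionTrace:
    records: list[dict] = field(default_factory=list)

    def log(self, action: str, term, waic_value: float, accepted: bool) -> None:
        self.records.append(
            {"action": action, "term": term, "waic": waic_value, "accepted": accepted}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _spec_with(base: ModelSpec, terms, interactions) -> ModelSpec:
    return ModelSpec(
        terms=tuple(terms),
        interactions=tuple(interactions),
        diversity_radius_m=base.diversity_radius_m,
        n_factors=base.n_factors,
        use_site=base.use_site,
        use_year=base.use_year,
        reference_class=base.reference_class,
    )


def stepwise_select(
    pool,
    counts: pd.DataFrame,
    features: pd.DataFrame,
    base: ModelSpec | None = None,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = SEARCH_SETTINGS,
    min_delta: float = 0.0,
    max_steps: int = 50,
) -> tuple[ModelSpec, SelectionTrace]:
    """Forward-backward stepwise structure search by WAIC.

    Starts from the intercept-only model; each cycle first tries the best
    single addition, then the best single removal, accepting any move that
    lowers WAIC by more than ``min_delta``.  Interaction candidates (term
    pairs in ``pool``) are only entertained while both main effects are in
    the model, and removing a main effect also removes its interactions.
    All fits reuse ``settings`` (a deliberately short schedule), so the
    search is deterministic given its seed.
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    base = base or ModelSpec.intercept_only(n_factors=1)
    mains = [t for t in pool if isinstance(t, str)]
    inters = [t for t in pool if not isinstance(t, str)]
    trace = SelectionTrace()
    cache: dict[tuple, float] = {}

    def score(terms, interactions) -> float:
        key = (tuple(sorted(terms)), tuple(sorted(interactions)))
        if key not in cache:
            spec = _spec_with(base, terms, interactions)
            post = fit_model(counts, features, spec, priors, settings)
            cache[key] = waic(post, counts)
        return cache[key]

    terms: list = []
    interactions: list = []
    current = score(terms, interactions)
    trace.log("start", None, current, True)

    for _ in range(max_steps):
        moved = False
        # forward: best single addition
        adds = [t for t in mains if t not in terms]
        adds += [t for t in inters
                 if t not in interactions and t[0] in terms and t[1] in terms]
        scored_adds = []
        for t in adds:
            nt = terms + [t] if isinstance(t, str) else terms
            ni = interactions + [t] if not isinstance(t, str) else interactions
            scored_adds.append((score(nt, ni), t))
        if scored_adds:
            best_w, best_t = min(scored_adds, key=lambda z: z[0])
            if best_w < current - min_delta:
                if isinstance(best_t, str):
                    terms.append(best_t)
                else:
                    interactions.append(best_t)
                current = best_w
                trace.log("add", best_t, best_w, True)
                moved = True
            elif scored_adds:
                trace.log("add", best_t, best_w, False)
        # backward: best single removal
        drops = list(interactions) + list(terms)
        scored_drops = []
        for t in drops:
            if isinstance(t, str):
                nt = [x for x in terms if x != t]
                ni = [x for x in interactions if t not in x]
            else:
                nt, ni = terms, [x for x in interactions if x != t]
            scored_drops.append((score(nt, ni), t))
        if scored_drops:
            best_w, best_t = min(scored_drops, key=lambda z: z[0])
            if best_w < current - min_delta:
                if isinstance(best_t, str):
                    terms = [x for x in terms if x != best_t]
                    interactions = [x for x in interactions if best_t not in x]
                else:
                    interactions = [x for x in interactions if x != best_t]
                current = best_w
                trace.log("drop", best_t, best_w, True)
                moved = True
        if not moved:
            break
    return _spec_with(base, terms, interactions), trace


def select_diversity_radius(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    radii_m=(500.0, 1000.0, 1500.0),
    base: ModelSpec | None = None,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = SEARCH_SETTINGS,
) -> tuple[float, pd.Series]:
    """Pick the circle radius whose single-diversity model has lowest WAIC.

    Ties go to the smallest radius.
    """
    radii = sorted(radii_m)
    base = base or ModelSpec.intercept_only(n_factors=1)
    scores = {}
    for r in radii:
        spec = ModelSpec(
            terms=("diversity",), interactions=(), diversity_radius_m=r,
            n_factors=base.n_factors, use_site=base.use_site, use_year=base.use_year,
        )
        post = fit_model(counts, features, spec, priors, settings)
        scores[r] = waic(post, counts)
    table = pd.Series(scores, name="waic")
    best = table.min()
    winner = min(r for r in radii if table[r] <= best + 1e-12)
    return winner, table


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    rmse: pd.Series  # per species
    relative_rmse: pd.Series  # % of observed MaxN range
    response_range: pd.DataFrame  # min/max per species
    folds: np.ndarray  # fold id per deployment

    @property
    def mean_rmse(self) -> float:
        return float(self.rmse.mean())


def rmse_relative(rmse: float, response_min: float, response_max: float) -> float:
    """RMSE as a percentage of the response range, to one decimal."""
    if response_max <= response_min:
        raise ValueError("response range must be positive")
    return round(100.0 * rmse / (response_max - response_min), 1)


def kfold_cv(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    spec: ModelSpec,
    k: int = 5,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = SEARCH_SETTINGS,
    seed: int = 0,
) -> CVResult:
    """K-fold cross-validated RMSE per species.

    Deployments are randomly partitioned into ``k`` folds; each fold is
    predicted by a model refit on the remainder, using the posterior mean
    of lambda with site/year intercepts at their sampled values (levels are
    shared across folds; a level absent from a training split predicts with
    its effect at zero, with a warning) and the latent term at its zero
    mean.
    """
    n = len(counts)
    if k < 2 or n < 2 * k:
        raise ValueError("need k >= 2 and at least two deployments per fold")
    rng = np.random.default_rng(seed)
    folds = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(folds)
    pred = np.empty(counts.shape)
    for f in range(k):
        test = folds == f
        train_feats = features.loc[~test]
        train_design = build_design_matrix(train_feats, spec)
        post = sample_posterior(
            counts.loc[~test],
            train_design,
            priors,
            settings,
            site=train_feats["site"] if spec.use_site else None,
            year=train_feats["year"] if spec.use_year else None,
            n_factors=spec.n_factors,
        )
        test_design = build_design_matrix(features.loc[test], spec, template=train_design)
        site_idx = year_idx = None
        if spec.use_site:
            lut = {lv: i for i, lv in enumerate(post.site_levels)}
            site_idx = np.array(
                [lut.get(s, -1) for s in features.loc[test, "site"]], dtype=np.int64
            )
        if spec.use_year:
            lut = {lv: i for i, lv in enumerate(post.year_levels)}
            year_idx = np.array(
                [lut.get(s, -1) for s in features.loc[test, "year"]], dtype=np.int64
            )
        for idx in (site_idx, year_idx):
            if idx is not None and np.any(idx < 0):
                warnings.warn(
                    "held-out rows with a site/year level unseen in training; "
                    "their random effect is taken as zero", stacklevel=2,
                )
        eta = post.linear_predictor(
            test_design.matrix, site_idx, year_idx, include_latent=False
        )
        pred[test] = np.exp(eta).mean(axis=0)
    y = counts.to_numpy(dtype=float)
    rmse = pd.Series(np.sqrt(((y - pred) ** 2).mean(axis=0)), index=counts.columns)
    rng_frame = pd.DataFrame({"min": y.min(axis=0), "max": y.max(axis=0)},
                             index=counts.columns)
    rel = pd.Series(
        {
            sp: rmse_relative(rmse[sp], rng_frame.loc[sp, "min"], rng_frame.loc[sp, "max"])
            if rng_frame.loc[sp, "max"] > rng_frame.loc[sp, "min"] else np.nan
            for sp in counts.columns
        }
    )
    return CVResult(rmse=rmse, relative_rmse=rel, response_range=rng_frame, folds=folds)


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------


def variance_partition(
    posterior: PosteriorSamples,
    design: DesignMatrix | None = None,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Share of explained linear-predictor variance per covariate group.

    Per draw and species, the variance over deployments of each group's
    partial predictor X_g beta_g plus the site, year and latent
    contributions are normalised to percentages summing to 100, then
    averaged over draws.  ``groups`` maps group name -> design column names
    and must cover all non-intercept columns without overlap; by default
    each column is its own group.
    """
    design = design or posterior.design
    if design is None:
        raise ValueError("a design matrix is required")
    cols = design.columns[1:]
    if groups is None:
        groups = {c: [c] for c in cols}
    listed = [c for g in groups.values() for c in g]
    if len(listed) != len(set(listed)):
        raise ValueError("groups overlap")
    if set(listed) != set(cols):
        missing = set(cols) - set(listed)
        raise ValueError(f"groups must cover all non-intercept columns; missing {missing}")

    theta = posterior.coefficient_draws()  # (D, p, S)
    D, _, S = theta.shape
    col_ix = {c: k for k, c in enumerate(design.columns)}
    parts = {}
    for gname, gcols in groups.items():
        ix = [col_ix[c] for c in gcols]
        Xg = design.matrix[:, ix]
        contrib = np.einsum("nk,dks->dns", Xg, theta[:, ix, :])
        parts[gname] = contrib.var(axis=1)  # (D, S)
    train = posterior.diagnostics.get("training_index")
    if train is not None and posterior.eps_site.shape[2] > 0:
        es = posterior.flat(posterior.eps_site)[:, train["site_idx"], :]
        parts["site"] = es.var(axis=1)
    if train is not None and posterior.eps_year.shape[2] > 0:
        ey = posterior.flat(posterior.eps_year)[:, train["year_idx"], :]
        parts["year"] = ey.var(axis=1)
    if posterior.n_factors:
        lat = np.einsum(
            "dnf,dsf->dns", posterior.flat(posterior.scores), posterior.flat(posterior.loadings)
        )
        parts["latent"] = lat.var(axis=1)
    names = list(parts)
    stacked = np.stack([parts[g] for g in names], axis=0)  # (G, D, S)
    total = stacked.sum(axis=0)
    total[total == 0] = np.nan
    pct = 100.0 * stacked / total
    return pd.DataFrame(
        np.nanmean(pct, axis=1).T, index=posterior.species, columns=names
    )
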