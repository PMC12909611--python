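"""Hierarchical latent-factor Poisson joint species distribution model.

For deployment i and species j the MaxN count is

    y_ij ~ Poisson(lambda_ij),
    log lambda_ij = alpha_j + sum_k beta_kj x_ki + eps_S(i)j + eps_Y(i)j
                    + u_i . v_j,

with normal N(0, 10^4) priors on intercepts and coefficients, site and year
random intercepts whose precisions carry Gamma(0.1, 0.1) priors, latent
deployment scores u_i ~ N(0, I) and species loadings v_j whose common
precision also carries a Gamma(0.1, 0.1) prior.  The residual species
covariance Omega = V V' induced by the loadings is the object of the
association analysis; it is invariant to rotation of the factors, so no
rotational identification is imposed on U and V themselves.

Sampling is an adaptive Metropolis-within-Gibbs: every scalar location
parameter (coefficient, random intercept, score, loading) takes a random
walk Metropolis step whose log step size adapts toward 44% acceptance
during the first half of burn-in and is frozen afterwards, while the three
precision components use exact conjugate Gamma draws.  The kernel is
numba-compiled; one chain is one kernel call with its own seed derived from
the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .design import DesignMatrix

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PosteriorSamples",
    "mcmc_schedule",
    "poisson_log_likelihood",
    "log_likelihood",
    "sample_posterior",
]


@dataclass(frozen=True)
class PriorSpec:
    """Fixed-effect normal prior and variance-component Gamma prior."""

    beta_mean: float = 0.0
    beta_var: float = 1.0e4
    var_shape: float = 0.1
    var_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.beta_var <= 0 or self.var_shape <= 0 or self.var_rate <= 0:
            raise ValueError("prior variance, shape and rate must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    iterations: int = 3000
    burn_in: int = 1000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.chains < 1:
            raise ValueError("at least one chain required")


def mcmc_schedule(settings: MCMCSettings) -> tuple[int, int]:
    """Retained draws per chain and in total.

    E.g. 30,000 iterations with 10,000 transient, thinned by 10, keep
    2000 per chain — 16,000 over 8 chains.
    """
    post = settings.iterations - settings.burn_in
    if post % settings.thinning:
        warnings.warn(
            "post-burn-in draws not divisible by thinning; flooring",
            stacklevel=2,
        )
    per_chain = post // settings.thinning
    return per_chain, per_chain * settings.chains


def poisson_log_likelihood(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Element-wise Poisson log pmf: y log lam - lam - log y!."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("Poisson rate must be positive (log link)")
    return y * np.log(lam) - lam - gammaln(y + 1.0)


def log_likelihood(counts, linear_predictor: np.ndarray) -> float:
    """Total Poisson log likelihood of a count matrix at log-rates."""
    y = np.asarray(getattr(counts, "values", counts), dtype=float)
    eta = np.asarray(linear_predictor, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("count and linear-predictor shapes differ")
    return float(poisson_log_likelihood(y, np.exp(eta)).sum())


# ---------------------------------------------------------------------------
# numba kernel: one chain
# ---------------------------------------------------------------------------

_TARGET_ACC = 0.44  # scalar random-walk optimum


@njit(cache=True)
def _run_chain(  # noqa: PLR0915 - one flat kernel keeps numba fast
    y, X, Xs, P_all, site_idx, year_idx, n_site, n_year, F,
    beta_var, a0, b0,
    n_iter, n_burn, thin, adapt_end, seed,
    theta0, U0, V0, Rall, PRall, Rinv_all,
):
    # Xs[j] is the design in species j's Fisher-preconditioned basis (its
    # columns are orthonormal under that species' curvature weights);
    # P_all[j] is the normal coefficient prior precision in that basis
    np.random.seed(seed)
    n, S = y.shape
    p = Xs.shape[2]

    theta = theta0.copy()
    PG = np.empty((p, S))  # prior-gradient bookkeeping for the quadratic form
    for j in range(S):
        PG[:, j] = P_all[j] @ theta[:, j]
    eps_s = np.zeros((n_site, S))
    eps_y = np.zeros((n_year, S))
    tau_s = 1.0
    tau_y = 1.0
    tau_v = 1.0
    U = U0.copy()
    V = V0.copy()

    M = np.empty((n, S))
    for j in range(S):
        M[:, j] = Xs[j] @ theta[:, j]
    for i in range(n):
        for j in range(S):
            if n_site > 0:
                M[i, j] += eps_s[site_idx[i], j]
            if n_year > 0:
                M[i, j] += eps_y[year_idx[i], j]
            for f in range(F):
                M[i, j] += U[i, f] * V[j, f]
    L = np.exp(M)

    ls_theta = np.full((p, S), -1.5)
    ls_es = np.full((n_site, S), -1.5)
    ls_ey = np.full((n_year, S), -1.5)
    ls_u = np.full((n, F), -1.0)
    ls_v = np.full((S, F), -1.0)
    acc_theta = np.zeros((p, S))

    # site/year membership sums of y, and member lists
    y_site = np.zeros((n_site, S))
    y_year = np.zeros((n_year, S))
    for i in range(n):
        for j in range(S):
            if n_site > 0:
                y_site[site_idx[i], j] += y[i, j]
            if n_year > 0:
                y_year[year_idx[i], j] += y[i, j]

    n_keep = (n_iter - n_burn) // thin
    out_theta = np.empty((n_keep, p, S))
    out_es = np.empty((n_keep, n_site, S))
    out_ey = np.empty((n_keep, n_year, S))
    out_sig_s = np.empty(n_keep)
    out_sig_y = np.empty(n_keep)
    out_U = np.empty((n_keep, n, F))
    out_V = np.empty((n_keep, S, F))
    out_sig_v = np.empty(n_keep)

    kept = 0
    n_theta_upd = 0.0
    for it in range(n_iter):
        adapting = it < adapt_end
        gam = 1.0 / (1.0 + 0.1 * it) ** 0.6 if adapting else 0.0

        # --- coefficients ---------------------------------------------------
        for k in range(p):
            for j in range(S):
                step = np.exp(ls_theta[k, j])
                delta = step * np.random.standard_normal()
                s1 = 0.0
                s2 = 0.0
                for i in range(n):
                    e = Xs[j, i, k] * delta
                    s1 += y[i, j] * e
                    s2 += L[i, j] * (np.exp(e) - 1.0)
                old = theta[k, j]
                logr = s1 - s2 - delta * PG[k, j] - 0.5 * delta * delta * P_all[j, k, k]
                a = np.exp(logr) if logr < 0.0 else 1.0
                if np.random.random() < a:
                    theta[k, j] = old + delta
                    for m in range(p):
                        PG[m, j] += P_all[j, m, k] * delta
                    for i in range(n):
                        M[i, j] += Xs[j, i, k] * delta
                        L[i, j] = np.exp(M[i, j])
                    if not adapting:
                        acc_theta[k, j] += 1.0
                if adapting:
                    ls_theta[k, j] += gam * (a - _TARGET_ACC)
        if not adapting:
            n_theta_upd += 1.0

        # --- site / year random intercepts ---------------------------------
        for lev in range(n_site):
            for j in range(S):
                step = np.exp(ls_es[lev, j])
                delta = step * np.random.standard_normal()
                lam_sum = 0.0
                for i in range(n):
                    if site_idx[i] == lev:
                        lam_sum += L[i, j]
                old = eps_s[lev, j]
                logr = (
                    y_site[lev, j] * delta
                    - (np.exp(delta) - 1.0) * lam_sum
                    + 0.5 * tau_s * (old * old - (old + delta) * (old + delta))
                )
                a = np.exp(logr) if logr < 0.0 else 1.0
                if np.random.random() < a:
                    eps_s[lev, j] = old + delta
                    for i in range(n):
                        if site_idx[i] == lev:
                            M[i, j] += delta
                            L[i, j] = np.exp(M[i, j])
                if adapting:
                    ls_es[lev, j] += gam * (a - _TARGET_ACC)
        for lev in range(n_year):
            for j in range(S):
                step = np.exp(ls_ey[lev, j])
                delta = step * np.random.standard_normal()
                lam_sum = 0.0
                for i in range(n):
                    if year_idx[i] == lev:
                        lam_sum += L[i, j]
                old = eps_y[lev, j]
                logr = (
                    y_year[lev, j] * delta
                    - (np.exp(delta) - 1.0) * lam_sum
                    + 0.5 * tau_y * (old * old - (old + delta) * (old + delta))
                )
                a = np.exp(logr) if logr < 0.0 else 1.0
                if np.random.random() < a:
                    eps_y[lev, j] = old + delta
                    for i in range(n):
                        if year_idx[i] == lev:
                            M[i, j] += delta
                            L[i, j] = np.exp(M[i, j])
                if adapting:
                    ls_ey[lev, j] += gam * (a - _TARGET_ACC)

        # --- recentring: exact Gibbs transfer between the intercept and the
        # --- random-intercept block (removes the alpha/eps ridge) -----------
        if n_site > 0:
            for j in range(S):
                alpha_j = 0.0
                for m in range(p):
                    alpha_j += Rinv_all[j, 0, m] * theta[m, j]
                sum_eps = 0.0
                for lev in range(n_site):
                    sum_eps += eps_s[lev, j]
                prec = 1.0 / beta_var + n_site * tau_s
                mu = (tau_s * sum_eps - alpha_j / beta_var) / prec
                d = mu + np.random.standard_normal() / np.sqrt(prec)
                for m in range(p):
                    theta[m, j] += d * Rall[j, m, 0]
                    PG[m, j] += d * PRall[j, m, 0]
                for lev in range(n_site):
                    eps_s[lev, j] -= d
        if n_year > 0:
            for j in range(S):
                alpha_j = 0.0
                for m in range(p):
                    alpha_j += Rinv_all[j, 0, m] * theta[m, j]
                sum_eps = 0.0
                for lev in range(n_year):
                    sum_eps += eps_y[lev, j]
                prec = 1.0 / beta_var + n_year * tau_y
                mu = (tau_y * sum_eps - alpha_j / beta_var) / prec
                d = mu + np.random.standard_normal() / np.sqrt(prec)
                for m in range(p):
                    theta[m, j] += d * Rall[j, m, 0]
                    PG[m, j] += d * PRall[j, m, 0]
                for lev in range(n_year):
                    eps_y[lev, j] -= d

        # --- conjugate precision draws --------------------------------------
        if n_site > 0:
            ss = 0.0
            for lev in range(n_site):
                for j in range(S):
                    ss += eps_s[lev, j] * eps_s[lev, j]
            tau_s = np.random.gamma(a0 + 0.5 * n_site * S, 1.0 / (b0 + 0.5 * ss))
        if n_year > 0:
            ss = 0.0
            for lev in range(n_year):
                for j in range(S):
                    ss += eps_y[lev, j] * eps_y[lev, j]
            tau_y = np.random.gamma(a0 + 0.5 * n_year * S, 1.0 / (b0 + 0.5 * ss))

        # --- latent scores and loadings -------------------------------------
        for f in range(F):
            for i in range(n):
                step = np.exp(ls_u[i, f])
                delta = step * np.random.standard_normal()
                s1 = 0.0
                s2 = 0.0
                for j in range(S):
                    e = V[j, f] * delta
                    s1 += y[i, j] * e
                    s2 += L[i, j] * (np.exp(e) - 1.0)
                old = U[i, f]
                logr = s1 - s2 + 0.5 * (old * old - (old + delta) * (old + delta))
                a = np.exp(logr) if logr < 0.0 else 1.0
                if np.random.random() < a:
                    U[i, f] = old + delta
                    for j in range(S):
                        M[i, j] += V[j, f] * delta
                        L[i, j] = np.exp(M[i, j])
                if adapting:
                    ls_u[i, f] += gam * (a - _TARGET_ACC)
            for j in range(S):
                step = np.exp(ls_v[j, f])
                delta = step * np.random.standard_normal()
                s1 = 0.0
                s2 = 0.0
                for i in range(n):
                    e = U[i, f] * delta
                    s1 += y[i, j] * e
                    s2 += L[i, j] * (np.exp(e) - 1.0)
                old = V[j, f]
                logr = s1 - s2 + 0.5 * tau_v * (old * old - (old + delta) * (old + delta))
                a = np.exp(logr) if logr < 0.0 else 1.0
                if np.random.random() < a:
                    V[j, f] = old + delta
                    for i in range(n):
                        M[i, j] += U[i, f] * delta
                        L[i, j] = np.exp(M[i, j])
                if adapting:
                    ls_v[j, f] += gam * (a - _TARGET_ACC)
        # recentring between the latent scores and the fixed effects: for
        # any design column x_k, shifting U[:, f] by c x_k while moving
        # theta_kj by -c v_jf leaves the likelihood unchanged; its exact
        # Gaussian conditional removes the score/covariate confounding ridge
        for f in range(F):
            for k in range(p):
                xu = 0.0
                xx = 0.0
                for i in range(n):
                    xu += X[i, k] * U[i, f]
                    xx += X[i, k] * X[i, k]
                tv = 0.0  # sum_j theta_kj v_jf
                vv = 0.0
                for j in range(S):
                    th_kj = 0.0
                    for m in range(p):
                        th_kj += Rinv_all[j, k, m] * theta[m, j]
                    tv += th_kj * V[j, f]
                    vv += V[j, f] * V[j, f]
                prec = xx + vv / beta_var
                mu = (-xu + tv / beta_var) / prec
                c = mu + np.random.standard_normal() / np.sqrt(prec)
                for i in range(n):
                    U[i, f] += c * X[i, k]
                for j in range(S):
                    shift = -c * V[j, f]
                    for m in range(p):
                        theta[m, j] += shift * Rall[j, m, k]
                        PG[m, j] += shift * PRall[j, m, k]

        if F > 0:
            ss = 0.0
            for j in range(S):
                for f in range(F):
                    ss += V[j, f] * V[j, f]
            tau_v = np.random.gamma(a0 + 0.5 * S * F, 1.0 / (b0 + 0.5 * ss))

        # --- retain ---------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0 and kept < n_keep:
            out_theta[kept] = theta
            out_es[kept] = eps_s
            out_ey[kept] = eps_y
            out_sig_s[kept] = 1.0 / tau_s
            out_sig_y[kept] = 1.0 / tau_y
            out_U[kept] = U
            out_V[kept] = V
            out_sig_v[kept] = 1.0 / tau_v
            kept += 1

    acc_rate = acc_theta / max(n_theta_upd, 1.0)
    return (out_theta, out_es, out_ey, out_sig_s, out_sig_y,
            out_U, out_V, out_sig_v, acc_rate)


# ---------------------------------------------------------------------------
# posterior container and driver
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, shaped (chains, draws, ...)."""

    species: list[str]
    columns: list[str]
    theta: np.ndarray  # (C, D, p, S) intercept row 0 = alpha
    eps_site: np.ndarray  # (C, D, n_site, S)
    eps_year: np.ndarray  # (C, D, n_year, S)
    sigma2_site: np.ndarray  # (C, D)
    sigma2_year: np.ndarray
    scores: np.ndarray  # (C, D, n, F)
    loadings: np.ndarray  # (C, D, S, F)
    sigma2_loadings: np.ndarray
    site_levels: list
    year_levels: list
    settings: MCMCSettings
    design: DesignMatrix | None = None
    acceptance: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return self.theta.shape[1]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[-1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Pool chains: (C, D, ...) -> (C*D, ...)."""
        return arr.reshape((-1,) + arr.shape[2:])

    def coefficient_draws(self) -> np.ndarray:
        """(C*D, p, S) pooled coefficient draws (row 0 is the intercept)."""
        return self.flat(self.theta)

    def loading_draws(self) -> np.ndarray:
        return self.flat(self.loadings)

    def linear_predictor(
        self,
        X: np.ndarray,
        site_idx: np.ndarray | None = None,
        year_idx: np.ndarray | None = None,
        include_latent: bool = True,
    ) -> np.ndarray:
        """Per-draw log-rates (C*D, n, S) at design rows X.

        Random intercepts are added for rows with known site/year levels;
        the latent term uses the fitted per-deployment scores only when
        ``include_latent`` (training rows), otherwise its zero-mean marginal.
        """
        theta = self.coefficient_draws()
        eta = np.einsum("nk,dks->dns", X, theta)
        if site_idx is not None and self.eps_site.shape[2] > 0:
            es = self.flat(self.eps_site)
            valid = site_idx >= 0
            eta[:, valid, :] += es[:, site_idx[valid], :]
        if year_idx is not None and self.eps_year.shape[2] > 0:
            ey = self.flat(self.eps_year)
            valid = year_idx >= 0
            eta[:, valid, :] += ey[:, year_idx[valid], :]
        if include_latent and self.n_factors:
            U = self.flat(self.scores)
            V = self.flat(self.loadings)
            eta += np.einsum("dnf,dsf->dns", U, V)
        return eta

    def fitted_linear_predictor(self, include_latent: bool = True) -> np.ndarray:
        """Per-draw log-rates at the training design."""
        if self.design is None:
            raise ValueError("posterior carries no training design")
        train = self.diagnostics["training_index"]
        return self.linear_predictor(
            self.design.matrix, train["site_idx"], train["year_idx"],
            include_latent=include_latent,
        )


def _level_index(labels, levels) -> np.ndarray:
    lut = {lv: i for i, lv in enumerate(levels)}
    return np.array([lut.get(x, -1) for x in labels], dtype=np.int64)


def _chain_seed(master: int, chain: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(chain,)).generate_state(1)[0] % (2**31))


def sample_prior(
    design: DesignMatrix,
    species: list[str],
    priors: PriorSpec,
    settings: MCMCSettings,
    n_site: int = 0,
    n_year: int = 0,
    n_factors: int = 0,
    n_deployments: int = 0,
) -> PosteriorSamples:
    """Draw directly from the priors (likelihood disabled).

    Coefficients are iid N(0, 10^4); each variance component is the inverse
    of a Gamma(0.1, 0.1) precision with its effects drawn at that scale.
    """
    per_chain, _ = mcmc_schedule(settings)
    C, D = settings.chains, per_chain
    p, S, F = design.n_columns, len(species), n_factors
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed, spawn_key=(9,)))
    tau = rng.gamma(priors.var_shape, 1 / priors.var_rate, size=(3, C, D))
    sig_s, sig_y, sig_v = 1 / tau
    theta = rng.normal(priors.beta_mean, np.sqrt(priors.beta_var), size=(C, D, p, S))
    eps_s = rng.normal(0, np.sqrt(sig_s)[..., None, None], size=(C, D, n_site, S))
    eps_y = rng.normal(0, np.sqrt(sig_y)[..., None, None], size=(C, D, n_year, S))
    V = rng.normal(0, np.sqrt(sig_v)[..., None, None], size=(C, D, S, F))
    U = rng.standard_normal((C, D, n_deployments, F))
    return PosteriorSamples(
        species=list(species), columns=list(design.columns),
        theta=theta, eps_site=eps_s, eps_year=eps_y,
        sigma2_site=sig_s, sigma2_year=sig_y,
        scores=U, loadings=V, sigma2_loadings=sig_v,
        site_levels=list(range(n_site)), year_levels=list(range(n_year)),
        settings=settings, design=design,
    )


def sample_posterior(
    counts: pd.DataFrame,
    design: DesignMatrix,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings = MCMCSettings(),
    site=None,
    year=None,
    n_factors: int = 2,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Fit the joint model by MCMC.

    ``counts`` is deployments x species; ``site`` and ``year`` are optional
    per-deployment labels switching on the corresponding random intercepts.
    Step sizes adapt during the first half of burn-in only, so retained
    draws come from a fixed kernel; each chain runs from its own seed
    derived from ``settings.seed``.
    """
    y = counts.to_numpy()
    if y.shape[0] != design.matrix.shape[0]:
        raise ValueError("count rows and design rows differ")
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.number):
        raise ValueError("counts must be nonnegative")
    species = list(counts.columns)
    n, S = y.shape
    site_levels = sorted(set(site)) if site is not None else []
    year_levels = sorted(set(year)) if year is not None else []
    site_idx = _level_index(site, site_levels) if site is not None else np.full(n, -1, np.int64)
    year_idx = _level_index(year, year_levels) if year is not None else np.full(n, -1, np.int64)

    if prior_only:
        out = sample_prior(
            design, species, priors, settings,
            n_site=len(site_levels), n_year=len(year_levels),
            n_factors=n_factors, n_deployments=n,
        )
        out.site_levels, out.year_levels = site_levels, year_levels
        return out

    per_chain, _ = mcmc_schedule(settings)
    F = n_factors
    p = design.n_columns
    theta0 = np.zeros((p, S))
    theta0[0] = np.log(y.mean(axis=0) + 0.05)
    init_rng = np.random.default_rng(np.random.SeedSequence(settings.seed, spawn_key=(7,)))
    U0 = 0.01 * init_rng.standard_normal((n, F))
    V0 = 0.01 * init_rng.standard_normal((S, F))
    adapt_end = settings.burn_in // 2

    # precondition the coefficient block per species: sample in the basis
    # that orthonormalises the design under that species' approximate
    # Fisher curvature (Poisson weights estimated as y + 1/2), with the
    # N(0, beta_var I) prior mapped exactly into it
    X = design.matrix
    Xs = np.empty((S, n, p))
    P_all = np.empty((S, p, p))
    gamma0 = np.empty((p, S))
    Rall = np.empty((S, p, p))
    PRall = np.empty((S, p, p))
    Rinv_all = np.empty((S, p, p))
    for j in range(S):
        w = y[:, j].astype(float) + 0.5
        A = (X * w[:, None]).T @ X + np.eye(p) / priors.beta_var
        Rmat = np.linalg.cholesky(A).T  # theta = Rinv gamma
        Rinv = np.linalg.inv(Rmat)
        Rall[j] = Rmat
        Rinv_all[j] = Rinv
        Xs[j] = X @ Rinv
        P_all[j] = (Rinv.T @ Rinv) / priors.beta_var
        PRall[j] = P_all[j] @ Rmat
        gamma0[:, j] = Rmat @ theta0[:, j]

    res = [
        _run_chain(
            np.ascontiguousarray(y, dtype=np.float64),
            np.ascontiguousarray(X, dtype=np.float64),
            np.ascontiguousarray(Xs),
            np.ascontiguousarray(P_all),
            site_idx, year_idx, len(site_levels), len(year_levels), F,
            priors.beta_var, priors.var_shape, priors.var_rate,
            settings.iterations, settings.burn_in, settings.thinning,
            adapt_end, _chain_seed(settings.seed, c),
            gamma0, U0, V0, Rall, PRall, Rinv_all,
        )
        for c in range(settings.chains)
    ]
    stack = lambda i: np.stack([r[i] for r in res])  # noqa: E731
    acc = stack(8)
    # map coefficient draws back to the design basis, species by species
    gam = stack(0)  # (C, D, p, S)
    theta_draws = np.empty_like(gam)
    for j in range(S):
        theta_draws[:, :, :, j] = gam[:, :, :, j] @ Rinv_all[j].T
    if np.any((acc < 0.05) | (acc > 0.95)):
        warnings.warn(
            "some coefficient acceptance rates fell outside [0.05, 0.95] "
            "after adaptation", stacklevel=2,
        )
    return PosteriorSamples(
        species=species, columns=list(design.columns),
        theta=theta_draws, eps_site=stack(1), eps_year=stack(2),
        sigma2_site=stack(3), sigma2_year=stack(4),
        scores=stack(5), loadings=stack(6), sigma2_loadings=stack(7),
        site_levels=site_levels, year_levels=year_levels,
        settings=settings, design=design, acceptance=acc,
        diagnostics={
            "training_index": {"site_idx": site_idx, "year_idx": year_idx},
        },
    )
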