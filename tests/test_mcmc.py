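import numpy as np
import pandas as pd
import pytest

from seascapejsdm.design import ModelSpec, build_design_matrix
from seascapejsdm.mcmc import (
    MCMCSettings,
    PriorSpec,
    log_likelihood,
    mcmc_schedule,
    poisson_log_likelihood,
    sample_posterior,
)


class TestSchedule:
    def test_study_schedule(self):
        per_chain, total = mcmc_schedule(
            MCMCSettings(chains=8, iterations=30_000, burn_in=10_000, thinning=10)
        )
        assert per_chain == 2000
        assert total == 16_000

    @pytest.mark.parametrize(
        "chains,iters,burn,thin,per,total",
        [(1, 100, 0, 1, 100, 100), (4, 30_000, 10_000, 20, 1000, 4000)],
    )
    def test_arithmetic(self, chains, iters, burn, thin, per, total):
        got = mcmc_schedule(MCMCSettings(chains=chains, iterations=iters,
                                         burn_in=burn, thinning=thin))
        assert got == (per, total)

    def test_non_divisible_floors_with_warning(self):
        with pytest.warns(UserWarning):
            per, _ = mcmc_schedule(MCMCSettings(chains=1, iterations=105,
                                                burn_in=0, thinning=10))
        assert per == 10

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            MCMCSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCSettings(thinning=0)


class TestLogLikelihood:
    def test_closed_forms(self):
        assert poisson_log_likelihood(0, 1.0) == pytest.approx(-1.0)
        assert poisson_log_likelihood(2, 2.0) == pytest.approx(-2 + np.log(2))

    def test_matrix_matches_cellwise_sum(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3, size=(3, 4))
        eta = rng.normal(0.5, 0.3, size=(3, 4))
        want = sum(
            float(poisson_log_likelihood(y[i, j], np.exp(eta[i, j])))
            for i in range(3)
            for j in range(4)
        )
        assert log_likelihood(y, eta) == pytest.approx(want)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_log_likelihood(1, 0.0)


def _simple_design(n, seed=0, p_extra=2):
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame({
        "depth_m": rng.uniform(5, 100, n),
        "boundary_dist_m": rng.uniform(0, 300, n),
    })
    terms = ("depth", "boundary_dist")[:p_extra]
    return build_design_matrix(feats, ModelSpec(terms=terms))


class TestSampler:
    def test_prior_only_beta_sd_near_100(self):
        dm = _simple_design(50)
        counts = pd.DataFrame({"a": np.zeros(50, dtype=int)})
        post = sample_posterior(
            counts, dm,
            settings=MCMCSettings(chains=2, iterations=2100, burn_in=100, seed=3),
            n_factors=0, prior_only=True,
        )
        sd = post.coefficient_draws().std()
        assert abs(sd - 100.0) < 5.0  # prior variance 10^4

    def test_intercept_only_recovers_mean_five(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame({"a": rng.poisson(5.0, size=200)})
        feats = pd.DataFrame({"depth_m": rng.uniform(0, 1, 200)})
        dm = build_design_matrix(feats, ModelSpec.intercept_only())
        post = sample_posterior(
            counts, dm,
            settings=MCMCSettings(chains=2, iterations=2000, burn_in=500, seed=0),
            n_factors=0,
        )
        lam_hat = np.exp(post.coefficient_draws()[:, 0, 0]).mean()
        assert lam_hat == pytest.approx(counts["a"].mean(), abs=0.3)

    def test_posterior_mean_matches_ml_fit_for_large_counts(self):
        # no random effects, no factors, informative data: posterior mean of
        # beta approaches the maximum-likelihood Poisson regression solution
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 400
        dm = _simple_design(n, seed=2)
        eta = dm.matrix @ np.array([1.5, 0.4, -0.3])
        counts = pd.DataFrame({"a": rng.poisson(np.exp(eta))})
        post = sample_posterior(
            counts, dm,
            settings=MCMCSettings(chains=2, iterations=3000, burn_in=1000, seed=1),
            n_factors=0,
        )
        bayes = post.coefficient_draws()[:, :, 0].mean(axis=0)
        ml = sm.GLM(counts["a"], dm.matrix, family=sm.families.Poisson()).fit().params
        np.testing.assert_allclose(bayes, ml, atol=0.03)

    def test_same_seed_reproduces_draws(self):
        rng = np.random.default_rng(3)
        dm = _simple_design(60, seed=3)
        counts = pd.DataFrame({
            "a": rng.poisson(2, 60), "b": rng.poisson(1, 60)
        })
        settings = MCMCSettings(chains=2, iterations=400, burn_in=200, seed=9)
        site = ["A"] * 30 + ["B"] * 30
        kw = dict(site=site, n_factors=1)
        p1 = sample_posterior(counts, dm, settings=settings, **kw)
        p2 = sample_posterior(counts, dm, settings=settings, **kw)
        np.testing.assert_array_equal(p1.theta, p2.theta)
        np.testing.assert_array_equal(p1.loadings, p2.loadings)
        p3 = sample_posterior(
            counts, dm, settings=MCMCSettings(chains=2, iterations=400,
                                              burn_in=200, seed=10), **kw)
        assert not np.array_equal(p1.theta, p3.theta)

    def test_count_design_mismatch_rejected(self):
        dm = _simple_design(20)
        counts = pd.DataFrame({"a": np.zeros(19, dtype=int)})
        with pytest.raises(ValueError):
            sample_posterior(counts, dm, settings=MCMCSettings(
                chains=1, iterations=20, burn_in=10))


def test_beta_rmse_shrinks_with_sample_size():
    """Posterior-mean coefficient error decreases from n = 100 to n = 600."""
    from helpers import make_dataset
    from seascapejsdm.synthetic import (
        SyntheticConfig,
        generate_bathymetry,
        generate_substratum_probabilities,
        sample_deployments,
        default_cutoffs,
    )
    from seascapejsdm.metrics import classify_patches, deployment_features

    def features_for(per_stratum, seed):
        cfg = SyntheticConfig(seed=seed, deployments_per_stratum=per_stratum)
        bathy = generate_bathymetry(cfg)
        sub = generate_substratum_probabilities(bathy, cfg)
        dep = sample_deployments(bathy, cfg)
        pm = classify_patches(sub, default_cutoffs())
        return deployment_features(dep, sub, pm, bathy)

    spec = ModelSpec(terms=("depth", "boundary_dist"), n_factors=1)
    settings = MCMCSettings(chains=2, iterations=1500, burn_in=500, seed=0)

    def rmse(per_stratum, rep):
        feats = features_for(per_stratum, seed=40 + rep)
        data = make_dataset(feats, n_species=3, seed=50 + rep, spec=spec)
        post = sample_posterior(
            data["counts"], data["design"], settings=settings,
            site=feats["site"], year=feats["year"], n_factors=1,
        )
        est = post.coefficient_draws().mean(axis=0)[1:]
        return np.sqrt(((est - data["true"].beta) ** 2).mean())

    small = np.mean([rmse(17, r) for r in range(2)])  # ~100 deployments
    large = np.mean([rmse(100, r) for r in range(2)])  # 600 deployments
    assert large < small


class TestLatentStructure:
    def test_residual_covariance_rotation_invariant(self):
        # Omega = V V' is unchanged by an orthogonal rotation of the factors
        rng = np.random.default_rng(4)
        V = rng.normal(size=(200, 5, 2))
        theta = rng.uniform(0, 2 * np.pi)
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        omega = np.einsum("dif,djf->dij", V, V)
        omega_rot = np.einsum("dif,djf->dij", V @ Q, V @ Q)
        np.testing.assert_allclose(omega, omega_rot, atol=1e-12)

    def test_species_relabelling_permutes_summaries(self, dataset):
        # deterministic post-processing is equivariant under species order
        from seascapejsdm.associations import (
            residual_correlation_draws,
            screen_associations,
        )
        from seascapejsdm.evaluation import fit_model

        post = fit_model(
            dataset["counts"], dataset["features"], dataset["spec"],
            settings=MCMCSettings(chains=1, iterations=300, burn_in=100, seed=0),
        )
        R = residual_correlation_draws(post.loading_draws())
        assoc = screen_associations(R, species=post.species)
        perm = [3, 1, 4, 0, 2]
        R_perm = R[:, perm][:, :, perm]
        assoc_p = screen_associations(R_perm,
                                      species=[post.species[i] for i in perm])
        a = assoc.mean.loc["sp0", "sp2"]
        b = assoc_p.mean.loc["sp0", "sp2"]
        assert a == pytest.approx(b)
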