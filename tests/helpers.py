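"""Shared builders for simulation-based tests."""

import numpy as np

from seascapejsdm import ModelSpec, build_design_matrix
from seascapejsdm.synthetic import TrueParameters, simulate_counts


def make_dataset(features, n_species=5, n_factors=1, seed=0, beta_sd=0.3,
                 alpha=0.8, sigma_site=0.3, sigma_year=0.3, loadings=None,
                 spec=None):
    """Simulate counts from known parameters on a given feature table."""
    spec = spec or ModelSpec.final_model(n_factors=n_factors)
    dm = build_design_matrix(features, spec)
    rng = np.random.default_rng(seed)
    if loadings is None and n_factors:
        loadings = rng.normal(0, 0.5, size=(n_species, n_factors))
    true = TrueParameters(
        species=[f"sp{j}" for j in range(n_species)],
        alpha=np.full(n_species, alpha),
        beta=rng.normal(0, beta_sd, size=(dm.n_columns - 1, n_species)),
        beta_columns=dm.columns[1:],
        sigma_site=sigma_site,
        sigma_year=sigma_year,
        loadings=loadings,
    )
    sim = simulate_counts(dm.matrix[:, 1:], true, features["site"],
                          features["year"], seed=seed + 1)
    sim.counts.index = dm.index
    return {"spec": spec, "design": dm, "true": true, "sim": sim,
            "counts": sim.counts, "features": features}
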