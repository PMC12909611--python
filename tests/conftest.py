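import numpy as np
import pandas as pd
import pytest

from seascapejsdm import (
    classify_patches,
    deployment_features,
    generate_bathymetry,
    generate_substratum_probabilities,
    sample_deployments,
)
from seascapejsdm.synthetic import SyntheticConfig, default_cutoffs

from helpers import make_dataset  # noqa: E402


@pytest.fixture(scope="session")
def seascape():
    """A small synthetic seascape with 120 deployments (20 per stratum)."""
    cfg = SyntheticConfig(seed=11)
    bathy = generate_bathymetry(cfg)
    sub = generate_substratum_probabilities(bathy, cfg)
    deployments = sample_deployments(bathy, cfg)
    patchmap = classify_patches(sub, default_cutoffs())
    features = deployment_features(deployments, sub, patchmap, bathy)
    return {
        "config": cfg,
        "bathy": bathy,
        "sub": sub,
        "patchmap": patchmap,
        "deployments": deployments,
        "features": features,
    }


@pytest.fixture(scope="session")
def seascape300():
    """A larger design: 50 deployments per stratum (n = 300)."""
    cfg = SyntheticConfig(seed=23, deployments_per_stratum=50)
    bathy = generate_bathymetry(cfg)
    sub = generate_substratum_probabilities(bathy, cfg)
    deployments = sample_deployments(bathy, cfg)
    patchmap = classify_patches(sub, default_cutoffs())
    features = deployment_features(deployments, sub, patchmap, bathy)
    return {"config": cfg, "bathy": bathy, "sub": sub, "patchmap": patchmap,
            "deployments": deployments, "features": features}


@pytest.fixture(scope="session")
def dataset(seascape):
    return make_dataset(seascape["features"], seed=5)


@pytest.fixture()
def toy_counts():
    """Tiny handcrafted count matrix with site/year labels."""
    counts = pd.DataFrame(
        {
            "cod": [3, 0, 1, 2, 0, 4, 1, 0],
            "haddock": [0, 0, 0, 1, 0, 0, 0, 0],
            "whiting": [2, 2, 3, 1, 4, 2, 1, 3],
        },
        index=[f"d{i}" for i in range(8)],
    )
    site = np.array(["A", "A", "A", "A", "B", "B", "B", "B"])
    year = np.array([2021, 2021, 2022, 2022, 2021, 2021, 2022, 2022])
    return counts, site, year
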