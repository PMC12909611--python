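"""Reading and writing the pipeline's file formats.

Rasters travel as single-band ESRI ASCII grids (one file per substratum
class plus bathymetry), tables as CSV, configuration as YAML.  Validation
happens at read time so a broken input fails before any modelling starts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import SubstratumRaster
from .raster import Raster, read_ascii_grid, write_ascii_grid

DEPLOYMENT_COLUMNS = ["deployment_id", "site", "year", "x", "y", "depth_m", "stratum"]


def write_substratum_rasters(directory, sub: SubstratumRaster) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, cls in enumerate(sub.classes):
        p = directory / f"substratum_{cls}.asc"
        write_ascii_grid(p, Raster(sub.geometry, sub.probabilities[k], sub.mask))
        paths.append(p)
    return paths


def read_substratum_rasters(paths, classes: list[str]) -> SubstratumRaster:
    """Load per-class probability grids, enforcing alignment and [0, 1]."""
    if len(paths) != len(classes):
        raise ValueError("one raster path per class required")
    rasters = [read_ascii_grid(p) for p in paths]
    first = rasters[0]
    for p, r in zip(paths, rasters):
        if not r.aligned_with(first):
            raise ValueError(f"raster {p} is not aligned with {paths[0]}")
        vals = r.values[r.mask]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError(f"raster {p} holds probabilities outside [0, 1]")
    mask = np.logical_and.reduce([r.mask for r in rasters])
    return SubstratumRaster(
        classes=list(classes),
        probabilities=np.stack([r.values for r in rasters]),
        geometry=first.geometry,
        mask=mask,
    )


def write_deployments(path, deployments: pd.DataFrame) -> None:
    deployments.to_csv(path, index=False)


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DEPLOYMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"deployment table missing column(s): {sorted(missing)}")
    if df["deployment_id"].duplicated().any():
        raise ValueError("duplicate deployment ids")
    return df


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.rename_axis("deployment_id").to_csv(path)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate deployment ids in count matrix")
    vals = df.to_numpy()
    if np.any(vals < 0):
        raise ValueError("MaxN counts must be nonnegative")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("MaxN counts must be integers")
    return df.astype(int)


def write_posterior(directory, posterior) -> Path:
    """One CSV per parameter block (draws pooled over chains) + a manifest."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    C, D, p, S = posterior.theta.shape
    theta = posterior.coefficient_draws().reshape(C * D, p * S)
    cols = [f"{c}|{s}" for c in posterior.columns for s in posterior.species]
    pd.DataFrame(theta, columns=cols).to_csv(directory / "coefficients.csv", index=False)
    F = posterior.n_factors
    if F:
        V = posterior.loading_draws().reshape(C * D, S * F)
        vcols = [f"{s}|f{f}" for s in posterior.species for f in range(F)]
        pd.DataFrame(V, columns=vcols).to_csv(directory / "loadings.csv", index=False)
    pd.DataFrame(
        {
            "sigma2_site": posterior.flat(posterior.sigma2_site),
            "sigma2_year": posterior.flat(posterior.sigma2_year),
            "sigma2_loadings": posterior.flat(posterior.sigma2_loadings),
        }
    ).to_csv(directory / "variance_components.csv", index=False)
    manifest = {
        "chains": C,
        "draws_per_chain": D,
        "species": posterior.species,
        "columns": posterior.columns,
        "n_factors": F,
        "settings": vars(posterior.settings) | {},
        "site_levels": [str(x) for x in posterior.site_levels],
        "year_levels": [str(x) for x in posterior.year_levels],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return directory
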