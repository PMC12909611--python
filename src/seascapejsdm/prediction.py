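"""Gridded prediction, single-covariate response curves, and area summaries.

Predictions condition the random intercepts on chosen site/year levels
(e.g. the mapped year), while the deployment-specific latent scores are
marginalised at their zero mean — maps show the expected MaxN surface under
the fixed and random structure.  Cell covariates (dominant substratum,
boundary distance, surrounding patch diversity) are computed with the same
definitions as the deployment features, so training and prediction scales
agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.signal import oaconvolve

from .design import ModelSpec, build_design_matrix
from .metrics import PatchMap, SubstratumRaster, shoreline_cells, slope_aspect
from .mcmc import PosteriorSamples
from .raster import Raster


def _disk_kernel(radius_m: float, cell_size: float) -> np.ndarray:
    r_cells = radius_m / cell_size
    k = int(np.floor(r_cells))
    dr, dc = np.mgrid[-k : k + 1, -k : k + 1]
    return (dr**2 + dc**2 <= r_cells**2).astype(float)


def windowed_shannon(patchmap: PatchMap, radius_m: float) -> np.ndarray:
    """Shannon diversity H of dominant classes in a moving circular window.

    Matches the per-deployment circle computation at every cell centre
    (cells outside the study area or without a label are excluded); NaN
    where the window holds no eligible cell.
    """
    kernel = _disk_kernel(radius_m, patchmap.geometry.cell_size)
    eligible = (patchmap.mask & (patchmap.dominant >= 0)).astype(float)
    denom = oaconvolve(eligible, kernel, mode="same")
    H = np.zeros(patchmap.dominant.shape)
    for c in range(len(patchmap.classes)):
        onehot = (eligible > 0) & (patchmap.dominant == c)
        cnt = oaconvolve(onehot.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.clip(cnt / denom, 0.0, 1.0)
        term = np.where(p > 1e-9, -p * np.log(np.maximum(p, 1e-300)), 0.0)
        H += np.where(denom > 0.5, term, 0.0)
    H[denom < 0.5] = np.nan
    return H


def cell_features(
    patchmap: PatchMap,
    bathy: Raster,
    radii_m=(500.0,),
) -> pd.DataFrame:
    """Model covariates for every in-mask cell of the seascape."""
    geom = patchmap.geometry
    cell = geom.cell_size
    slope, aspect = slope_aspect(bathy)
    bdist = distance_transform_edt(~patchmap.boundary) * cell
    shore = shoreline_cells(patchmap.mask)
    if shore.any():
        sdist = distance_transform_edt(~shore) * cell
    else:
        sdist = np.full(patchmap.mask.shape, np.nan)
    Hs = {r: windowed_shannon(patchmap, r) for r in radii_m}
    rows, cols = np.nonzero(patchmap.mask)
    dom = patchmap.dominant[rows, cols]
    feats = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "depth_m": bathy.values[rows, cols],
            "substratum": [patchmap.classes[i] if i >= 0 else None for i in dom],
            "boundary_dist_m": bdist[rows, cols],
            "shore_dist_m": sdist[rows, cols],
            "slope_deg": slope.values[rows, cols],
            "aspect_deg": aspect.values[rows, cols],
        }
    )
    for r, H in Hs.items():
        feats[f"H_{int(r)}"] = H[rows, cols]
    return feats


@dataclass
class PredictionRaster:
    """Per-species posterior-mean expected MaxN over the seascape."""

    species: list[str]
    lam: np.ndarray  # (S, nrow, ncol); NaN where not predicted
    valid: np.ndarray  # cells actually predicted
    geometry: object
    conditioning: dict

    def as_raster(self, species: str) -> Raster:
        j = self.species.index(species)
        return Raster(self.geometry, np.nan_to_num(self.lam[j]), self.valid.copy())


def _conditioning_indices(posterior: PosteriorSamples, conditioning: dict, n: int):
    site_idx = year_idx = None
    if conditioning.get("site") is not None and posterior.site_levels:
        if conditioning["site"] not in posterior.site_levels:
            raise ValueError(f"unknown site level {conditioning['site']!r}")
        site_idx = np.full(n, posterior.site_levels.index(conditioning["site"]), np.int64)
    if conditioning.get("year") is not None and posterior.year_levels:
        if conditioning["year"] not in posterior.year_levels:
            raise ValueError(f"unknown year level {conditioning['year']!r}")
        year_idx = np.full(n, posterior.year_levels.index(conditioning["year"]), np.int64)
    return site_idx, year_idx


def _posterior_mean_lambda(
    posterior: PosteriorSamples, X: np.ndarray, site_idx, year_idx, chunk: int = 4000
) -> np.ndarray:
    """Posterior mean of exp(eta) at design rows, latent term marginalised."""
    out = np.empty((X.shape[0], len(posterior.species)))
    for lo in range(0, X.shape[0], chunk):
        hi = min(lo + chunk, X.shape[0])
        eta = posterior.linear_predictor(
            X[lo:hi],
            site_idx[lo:hi] if site_idx is not None else None,
            year_idx[lo:hi] if year_idx is not None else None,
            include_latent=False,
        )
        out[lo:hi] = np.exp(eta).mean(axis=0)
    return out


def predict_grid(
    posterior: PosteriorSamples,
    patchmap: PatchMap,
    bathy: Raster,
    spec: ModelSpec,
    conditioning: dict | None = None,
) -> PredictionRaster:
    """Expected-MaxN heat map per species over the classified seascape.

    Cells with no dominant substratum, or with a class unseen at training,
    are left unpredicted (their count is reported in a warning).
    """
    conditioning = conditioning or {}
    radii = (spec.diversity_radius_m,) if "diversity" in spec.terms else ()
    feats = cell_features(patchmap, bathy, radii_m=radii or (spec.diversity_radius_m,))
    usable = feats["substratum"].notna()
    if "substratum" in spec.terms and posterior.design is not None:
        known = set(posterior.design.substratum_levels)
        unseen = usable & ~feats["substratum"].isin(known)
        if unseen.any():
            warnings.warn(
                f"{int(unseen.sum())} cells carry a substratum class unseen "
                "at training and are masked", stacklevel=2,
            )
        usable &= ~unseen
    feats_ok = feats.loc[usable]
    X = build_design_matrix(feats_ok, spec, template=posterior.design).matrix
    site_idx, year_idx = _conditioning_indices(posterior, conditioning, len(feats_ok))
    lam = _posterior_mean_lambda(posterior, X, site_idx, year_idx)

    S = len(posterior.species)
    grid = np.full((S, patchmap.geometry.nrow, patchmap.geometry.ncol), np.nan)
    rows = feats_ok["row"].to_numpy()
    cols = feats_ok["col"].to_numpy()
    for j in range(S):
        grid[j, rows, cols] = lam[:, j]
    valid = np.zeros(patchmap.mask.shape, dtype=bool)
    valid[rows, cols] = True
    return PredictionRaster(
        species=list(posterior.species), lam=grid, valid=valid,
        geometry=patchmap.geometry, conditioning=dict(conditioning),
    )


@dataclass
class ResponseCurve:
    """Predicted MaxN along one covariate, everything else held fixed."""

    covariate: str
    grid: np.ndarray
    mean: pd.DataFrame  # grid point x species
    lower: pd.DataFrame
    upper: pd.DataFrame
    fixed_values: dict
    substratum_class: str | None
    conditioning: dict


def response_curve(
    posterior: PosteriorSamples,
    features: pd.DataFrame,
    spec: ModelSpec,
    varying: str,
    n_points: int = 50,
    value_range: tuple[float, float] | None = None,
    substratum_class: str | None = None,
    conditioning: dict | None = None,
    level: float = 0.95,
    allow_extrapolation: bool = False,
) -> ResponseCurve:
    """Posterior response curve for one continuous covariate.

    Non-plotted covariates sit at their observed means, substratum at the
    training reference class unless ``substratum_class`` names another; the
    grid must stay within the observed range unless extrapolation is
    explicitly allowed.
    """
    if varying not in spec.terms:
        raise ValueError(f"{varying!r} is not a model term")
    conditioning = conditioning or {}
    col = spec.feature_column(varying)
    observed = features[col].to_numpy(float)
    lo, hi = (float(observed.min()), float(observed.max()))
    if value_range is not None:
        if not allow_extrapolation and (value_range[0] < lo or value_range[1] > hi):
            raise ValueError("requested range extends beyond the observed range")
        lo, hi = value_range
    grid = np.linspace(lo, hi, n_points)

    fixed = {}
    frame = {}
    for term in spec.terms:
        if term == "substratum":
            cls = substratum_class or posterior.design.reference
            if cls not in posterior.design.substratum_levels:
                raise ValueError(f"substratum class {cls!r} unseen at training")
            frame["substratum"] = [cls] * n_points
            fixed["substratum"] = cls
        else:
            c = spec.feature_column(term)
            if term == varying:
                frame[c] = grid
            else:
                frame[c] = np.full(n_points, features[c].mean())
                fixed[c] = float(features[c].mean())
    X = build_design_matrix(pd.DataFrame(frame), spec, template=posterior.design).matrix
    site_idx, year_idx = _conditioning_indices(posterior, conditioning, n_points)
    eta = posterior.linear_predictor(X, site_idx, year_idx, include_latent=False)
    lam = np.exp(eta)  # (D, n_points, S)
    alpha = 1.0 - level
    idx = pd.Index(grid, name=col)
    cols_ = posterior.species
    return ResponseCurve(
        covariate=varying,
        grid=grid,
        mean=pd.DataFrame(lam.mean(axis=0), index=idx, columns=cols_),
        lower=pd.DataFrame(np.quantile(lam, alpha / 2, axis=0), index=idx, columns=cols_),
        upper=pd.DataFrame(np.quantile(lam, 1 - alpha / 2, axis=0), index=idx, columns=cols_),
        fixed_values=fixed,
        substratum_class=substratum_class,
        conditioning=dict(conditioning),
    )


DEFAULT_PRESENCE_RULE = "P(MaxN >= 1) = 1 - exp(-lambda) >= 0.5"


def percent_area_present(
    pred: PredictionRaster,
    species: str | None = None,
    rule=None,
) -> pd.Series | float:
    """Percentage of the predicted area where a species is deemed present.

    The default rule calls a cell present when the posterior-mean Poisson
    occurrence probability 1 - exp(-lambda) reaches 0.5; any callable
    lambda-array -> bool-array may replace it.  The rule used is recorded on
    the result (``result.attrs['rule']``).
    """
    if not pred.valid.any():
        raise ValueError("prediction raster has no valid cells")
    if rule is None:
        desc = DEFAULT_PRESENCE_RULE
        rule = lambda lam: 1.0 - np.exp(-lam) >= 0.5  # noqa: E731
    else:
        desc = getattr(rule, "__doc__", None) or repr(rule)
    out = {}
    for j, sp in enumerate(pred.species):
        lam = pred.lam[j][pred.valid]
        out[sp] = round(100.0 * float(np.mean(rule(lam))), 1)
    res = pd.Series(out, name="percent_area_present")
    res.attrs["rule"] = desc
    if species is not None:
        return float(res[species])
    return res
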