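"""Synthetic seascapes, survey designs, and species counts with known truth.

The generator emulates the study system: a fjordic sea loch with a shoreline
on its western edge, bathymetry deepening offshore over six design depth
strata (0–116 m), six substratum classes whose probability surfaces are
smooth fields — soft sediments (mud, muddy sand, sand, gravel) with wide
fuzzy transition zones, rock and cobble with crisp edges — and a
depth-stratified baited-video survey with an equal number of deployments per
stratum.  Counts are drawn from the Poisson log-link joint model: species
intercepts and covariate coefficients, site and year random intercepts, and
a low-rank latent-factor residual that induces species associations.

One master seed is expanded into independent substreams per component so
stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .metrics import (
    DEPTH_STRATUM_EDGES,
    DEPTH_STRATUM_MAX,
    HARD_CUTOFF,
    SOFT_CUTOFF,
    SubstratumRaster,
    assign_depth_stratum,
)
from .raster import GridGeometry, Raster

HARD_CLASSES = ("rock", "cobble_boulder")
SOFT_CLASSES = ("mud", "muddy_sand", "sand", "gravel")
DEFAULT_CLASSES = SOFT_CLASSES + HARD_CLASSES

_STREAMS = ("bathymetry", "substratum", "deployments", "counts")


def default_cutoffs(classes=DEFAULT_CLASSES) -> dict[str, float]:
    """Per-class probability cutoffs: 0.25 for hard edges, 0.1 for fuzzy."""
    return {c: HARD_CUTOFF if c in HARD_CLASSES else SOFT_CUTOFF for c in classes}


@dataclass
class SyntheticConfig:
    """Raster extent, substratum smoothness, survey design, and seed."""

    nrow: int = 120
    ncol: int = 160
    cell_size: float = 25.0  # m; the real product's resolution is a free choice
    x_origin: float = 0.0
    y_origin: float = 0.0
    classes: tuple[str, ...] = DEFAULT_CLASSES
    # correlation length (cells) of each class's random field; soft sediments
    # are smoother, which widens their 0.1 < p < 0.9 transition zones
    smoothness: dict[str, float] = field(default_factory=lambda: {
        "mud": 12.0, "muddy_sand": 12.0, "sand": 10.0, "gravel": 9.0,
        "rock": 4.0, "cobble_boulder": 4.0,
    })
    # logistic transition widths: large for fuzzy classes, small for hard
    fuzziness: dict[str, float] = field(default_factory=lambda: {
        "mud": 0.9, "muddy_sand": 0.9, "sand": 0.8, "gravel": 0.7,
        "rock": 0.25, "cobble_boulder": 0.25,
    })
    depth_range: tuple[float, float] = (0.0, DEPTH_STRATUM_MAX)
    shore_cells: int = 4  # land strip width on the western edge
    deployments_per_stratum: int = 20
    sites: tuple[str, ...] = ("site_A", "site_B")
    years: tuple[int, ...] = (2021, 2022)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deployments_per_stratum < 1:
            raise ValueError("deployments per stratum must be >= 1")
        lo, hi = self.depth_range
        if not (0 <= lo < hi <= DEPTH_STRATUM_MAX):
            raise ValueError("depth range must lie within the 0-116 m design")
        if self.nrow < 8 or self.ncol < 8:
            raise ValueError("extent too small to contain the depth strata")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for a named pipeline component."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian noise."""
    g = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (g - g.mean()) / g.std()


def generate_bathymetry(config: SyntheticConfig) -> Raster:
    """Smooth depth field (m, positive downward) deepening offshore.

    The western ``shore_cells`` columns are land (masked out); in-mask depths
    span the configured range so all six strata are populated.
    """
    rng = config.rng("bathymetry")
    shape = (config.nrow, config.ncol)
    cols = np.arange(config.ncol)
    ramp = np.clip((cols - config.shore_cells) / (config.ncol - config.shore_cells - 1), 0, 1)
    base = np.broadcast_to(ramp, shape).astype(float)
    noise = _smooth_field(rng, shape, sigma=max(shape) / 12)
    depth = base + 0.18 * noise
    mask = np.broadcast_to(cols >= config.shore_cells, shape).copy()
    lo, hi = config.depth_range
    inm = depth[mask]
    depth = (depth - inm.min()) / (inm.max() - inm.min()) * (hi - lo) + lo
    depth = np.clip(depth, lo, hi)
    depth[~mask] = 0.0
    bathy = Raster(
        GridGeometry(config.x_origin, config.y_origin, config.cell_size,
                     config.nrow, config.ncol),
        depth,
        mask,
    )
    _check_strata_populated(bathy, config)
    return bathy


def _check_strata_populated(bathy: Raster, config: SyntheticConfig) -> None:
    strat = assign_depth_stratum(bathy.values[bathy.mask])
    counts = np.bincount(strat, minlength=7)[1:]
    lacking = np.nonzero(counts < config.deployments_per_stratum)[0] + 1
    if lacking.size:
        raise ValueError(
            f"depth stratum/strata {lacking.tolist()} hold fewer cells than "
            f"the {config.deployments_per_stratum} deployments requested"
        )


# depth (m) of peak affinity per class: rock/cobble shallow, mud deep
_DEPTH_PEAK = {"rock": 8.0, "cobble_boulder": 20.0, "gravel": 30.0,
               "sand": 45.0, "muddy_sand": 65.0, "mud": 95.0}


def generate_substratum_probabilities(
    bathy: Raster, config: SyntheticConfig
) -> SubstratumRaster:
    """One smooth probability surface per substratum class, aligned to the
    bathymetry grid.

    Each class combines a class-specific smooth random field with a depth
    affinity, squashed through a logistic whose width sets the fuzziness:
    soft-sediment classes get wide 0.1 < p < 0.9 transition zones, rock and
    cobble crisp ones.  Surfaces are softly rescaled so one or two classes
    dominate most cells while overlap zones persist; they need not sum to 1.
    """
    if not config.classes:
        raise ValueError("substratum class list is empty")
    if bathy.geometry.nrow != config.nrow or bathy.geometry.ncol != config.ncol:
        raise ValueError("bathymetry grid does not match the configured extent")
    rng = config.rng("substratum")
    shape = (config.nrow, config.ncol)
    depth = bathy.values
    span = config.depth_range[1] - config.depth_range[0]
    scores = np.empty((len(config.classes),) + shape)
    for k, cls in enumerate(config.classes):
        g = _smooth_field(rng, shape, config.smoothness.get(cls, 8.0))
        affinity = np.exp(-0.5 * ((depth - _DEPTH_PEAK.get(cls, 40.0)) / (0.35 * span)) ** 2)
        scores[k] = 4.0 * (g + 1.2 * (affinity - 0.5))
    # probability from each class's margin over its best competitor: the
    # locally winning class sits near 1, losers near 0, and cells close to a
    # tie form the transition zone, whose width is the class's fuzziness
    order = np.sort(scores, axis=0)
    best, second = order[-1], order[-2]
    probs = np.empty_like(scores)
    for k, cls in enumerate(config.classes):
        rival = np.where(scores[k] >= best, second, best)
        margin = scores[k] - rival
        probs[k] = 1.0 / (1.0 + np.exp(-margin / config.fuzziness.get(cls, 0.5)))
    probs[:, ~bathy.mask] = 0.0
    return SubstratumRaster(
        classes=list(config.classes),
        probabilities=probs,
        geometry=bathy.geometry,
        mask=bathy.mask.copy(),
    )


def sample_deployments(bathy: Raster, config: SyntheticConfig) -> pd.DataFrame:
    """Depth-stratified random deployment table: equal counts per stratum.

    Each deployment carries coordinates (cell centre), the depth at its
    cell, a site label (western/eastern basin) and a survey year.
    """
    rng = config.rng("deployments")
    strat = np.where(bathy.mask, assign_depth_stratum(bathy.values), 0)
    geom = bathy.geometry
    cx, cy = geom.cell_centres()
    records = []
    n_per = config.deployments_per_stratum
    for s in range(1, 7):
        rows, cols = np.nonzero(strat == s)
        if rows.size < n_per:
            raise ValueError(
                f"stratum {s} has {rows.size} eligible cells, fewer than the "
                f"{n_per} deployments requested"
            )
        pick = rng.choice(rows.size, size=n_per, replace=False)
        for r, c in zip(rows[pick], cols[pick]):
            records.append((cx[r, c], cy[r, c], float(bathy.values[r, c]), s))
    df = pd.DataFrame(records, columns=["x", "y", "depth_m", "stratum"])
    # sites split as north/south bands; years assigned uniformly at random
    n_sites = len(config.sites)
    site_idx = np.minimum(
        (np.asarray(df["y"]) - geom.y_origin)
        // (geom.nrow * geom.cell_size / n_sites),
        n_sites - 1,
    ).astype(int) if n_sites > 1 else np.zeros(len(df), dtype=int)
    df.insert(0, "deployment_id", [f"d{i:04d}" for i in range(len(df))])
    df.insert(1, "site", [config.sites[i] for i in site_idx])
    df.insert(2, "year", rng.choice(config.years, size=len(df)))
    return df


@dataclass
class TrueParameters:
    """Ground-truth coefficients of the generative abundance model."""

    species: list[str]
    alpha: np.ndarray  # (S,) intercepts on the log scale
    beta: np.ndarray  # (p, S) coefficients aligned to design columns
    beta_columns: list[str]
    sigma_site: float = 0.0
    sigma_year: float = 0.0
    loadings: np.ndarray | None = None  # (S, F) latent loadings v

    def __post_init__(self) -> None:
        S = len(self.species)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float).reshape(len(self.beta_columns), S)
        if self.alpha.shape != (S,):
            raise ValueError("alpha must hold one intercept per species")
        if self.sigma_site < 0 or self.sigma_year < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.loadings is not None:
            self.loadings = np.asarray(self.loadings, dtype=float)
            if self.loadings.shape[0] != S:
                raise ValueError("loadings must have one row per species")

    @property
    def n_factors(self) -> int:
        return 0 if self.loadings is None else self.loadings.shape[1]


@dataclass
class SimulatedCounts:
    """Counts plus the latent quantities that generated them."""

    counts: pd.DataFrame  # deployments x species, integer MaxN
    linear_predictor: np.ndarray  # (n, S) log lambda
    lam: np.ndarray  # (n, S)
    eps_site: np.ndarray  # (n_sites, S)
    eps_year: np.ndarray  # (n_years, S)
    scores: np.ndarray | None  # (n, F) latent u


def simulate_counts(
    design,
    params: TrueParameters,
    site: pd.Series | np.ndarray,
    year: pd.Series | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> SimulatedCounts:
    """Draw MaxN ~ Poisson(lambda) from the log-link joint model.

    log lambda_ij = alpha_j + x_i'beta_j + eps_S(i)j + eps_Y(i)j + u_i.v_j,
    with site/year intercepts and latent scores drawn fresh per call.
    ``design`` is a DesignMatrix or a plain (n, p) array matching
    ``params.beta_columns``.
    """
    X = np.asarray(getattr(design, "matrix", design), dtype=float)
    cols = list(getattr(design, "columns", params.beta_columns))
    if cols != params.beta_columns:
        raise ValueError("design columns do not match the parameter term list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, S = X.shape[0], len(params.species)

    sites, site_idx = np.unique(np.asarray(site), return_inverse=True)
    years, year_idx = np.unique(np.asarray(year), return_inverse=True)
    eps_site = rng.normal(0.0, params.sigma_site, size=(len(sites), S))
    eps_year = rng.normal(0.0, params.sigma_year, size=(len(years), S))

    eta = params.alpha[None, :] + X @ params.beta
    eta += eps_site[site_idx] + eps_year[year_idx]
    scores = None
    if params.n_factors:
        scores = rng.standard_normal((n, params.n_factors))
        eta += scores @ params.loadings.T
    with np.errstate(over="ignore"):
        lam = np.exp(eta)
    if not (np.all(np.isfinite(eta)) and np.all(np.isfinite(lam))):
        raise ValueError("non-finite linear predictor or rate")
    counts = pd.DataFrame(
        rng.poisson(lam), columns=params.species,
        index=getattr(design, "index", pd.RangeIndex(n)),
    )
    return SimulatedCounts(counts, eta, lam, eps_site, eps_year, scores)
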