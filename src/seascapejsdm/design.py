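"""Model terms and the deployments x columns design matrix.

The abundance model is a Poisson log-link regression shared across species:
substratum enters reference-coded (C classes -> C-1 columns), continuous
covariates are standardized to mean 0 / SD 1 (with the constants stored so
prediction uses the training scale), and interactions are products of the
coded columns.  The final model of the study pairs substratum, depth,
distance to the nearest patch boundary and surrounding patch diversity with
the depth x substratum, boundary x substratum and depth x diversity
interactions: with six substratum classes that is
1 + 5 + 1 + 1 + 1 + 5 + 5 + 1 = 20 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# term name -> feature column; diversity is special-cased by radius
_FEATURE_OF = {
    "depth": "depth_m",
    "boundary_dist": "boundary_dist_m",
    "shore_dist": "shore_dist_m",
    "slope": "slope_deg",
    "aspect": "aspect_deg",
}

CONTINUOUS_TERMS = tuple(_FEATURE_OF) + ("diversity",)


@dataclass
class ModelSpec:
    """Which terms enter the linear predictor, and the latent-factor rank."""

    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    diversity_radius_m: float = 500.0
    n_factors: int = 2
    use_site: bool = True
    use_year: bool = True
    spatial: bool = False  # structured spatial random effect: not provided
    reference_class: str | None = None  # default: alphabetically first

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            for t in (a, b):
                if t not in self.terms:
                    raise ValueError(
                        f"interaction ({a}, {b}) requires main effect {t!r}"
                    )
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")
        if self.spatial:
            raise NotImplementedError(
                "spatially structured random effects are not provided; the "
                "coordinate random effect was dropped in model selection"
            )

    @classmethod
    def final_model(cls, diversity_radius_m: float = 500.0, n_factors: int = 2) -> "ModelSpec":
        """The selected model: substratum, depth, boundary distance and
        surrounding patch diversity plus their three interactions."""
        return cls(
            terms=("substratum", "depth", "boundary_dist", "diversity"),
            interactions=(
                ("depth", "substratum"),
                ("boundary_dist", "substratum"),
                ("depth", "diversity"),
            ),
            diversity_radius_m=diversity_radius_m,
            n_factors=n_factors,
        )

    @classmethod
    def intercept_only(cls, n_factors: int = 2) -> "ModelSpec":
        return cls(terms=(), interactions=(), n_factors=n_factors)

    def feature_column(self, term: str) -> str:
        if term == "diversity":
            return f"H_{int(self.diversity_radius_m)}"
        if term in _FEATURE_OF:
            return _FEATURE_OF[term]
        raise KeyError(f"unknown continuous term {term!r}")


@dataclass
class DesignMatrix:
    """Coded design with the metadata needed to re-apply it at prediction."""

    matrix: np.ndarray  # (n, p)
    columns: list[str]
    index: pd.Index  # deployment ids
    spec: ModelSpec
    standardization: dict[str, tuple[float, float]]  # term -> (mean, sd)
    substratum_levels: list[str] = field(default_factory=list)
    reference: str | None = None

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def _coded_columns(
    features: pd.DataFrame,
    spec: ModelSpec,
    standardization: dict[str, tuple[float, float]] | None,
    levels: list[str] | None,
    reference: str | None,
):
    """Per-term coded blocks; fit standardization/levels when not supplied."""
    n = len(features)
    std = {} if standardization is None else dict(standardization)
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    for term in spec.terms:
        if term == "substratum":
            observed = features["substratum"]
            if observed.isna().any():
                raise ValueError("deployments without a dominant substratum class")
            if levels is None:
                levels = sorted(observed.unique())
                reference = spec.reference_class or levels[0]
                if reference not in levels:
                    raise ValueError(f"reference class {reference!r} not observed")
            unseen = set(observed) - set(levels)
            if unseen:
                raise ValueError(f"substratum level(s) not seen in training: {sorted(unseen)}")
            coded_levels = [lv for lv in levels if lv != reference]
            cols = np.column_stack(
                [(observed == lv).to_numpy(float) for lv in coded_levels]
            ) if coded_levels else np.empty((n, 0))
            blocks[term] = ([f"sub[{lv}]" for lv in coded_levels], cols)
        else:
            raw = features[spec.feature_column(term)].to_numpy(float)
            if term not in std:
                mu, sd = float(raw.mean()), float(raw.std(ddof=0))
                if sd == 0:
                    raise ValueError(f"covariate {term!r} is constant")
                std[term] = (mu, sd)
            mu, sd = std[term]
            name = term if term != "diversity" else f"H{int(spec.diversity_radius_m)}"
            blocks[term] = ([name], ((raw - mu) / sd)[:, None])
    return blocks, std, (levels or []), reference


def build_design_matrix(
    features: pd.DataFrame,
    spec: ModelSpec,
    template: DesignMatrix | None = None,
) -> DesignMatrix:
    """Assemble the intercept, main-effect and interaction columns.

    Passing a fitted ``template`` re-applies its standardization constants
    and substratum coding to new rows (prediction); unseen substratum levels
    raise.
    """
    blocks, std, levels, reference = _coded_columns(
        features,
        spec,
        template.standardization if template else None,
        template.substratum_levels or None if template else None,
        template.reference if template else None,
    )
    names: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones((len(features), 1))]
    for term in spec.terms:
        nm, block = blocks[term]
        names.extend(nm)
        cols.append(block)
    for a, b in spec.interactions:
        na, ba = blocks[a]
        nb, bb = blocks[b]
        prod = ba[:, :, None] * bb[:, None, :]
        names.extend(f"{x}:{y}" for x in na for y in nb)
        cols.append(prod.reshape(len(features), -1))
    X = np.hstack(cols)
    nonconst = X[:, 1:].std(axis=0) if X.shape[1] > 1 else np.array([])
    if template is None and np.any(nonconst == 0):
        bad = [names[1:][i] for i in np.nonzero(nonconst == 0)[0]]
        raise ValueError(f"constant non-intercept column(s): {bad}")
    index = (
        pd.Index(features["deployment_id"])
        if "deployment_id" in features
        else features.index
    )
    return DesignMatrix(
        matrix=X,
        columns=names,
        index=pd.Index(index),
        spec=spec,
        standardization=std,
        substratum_levels=levels,
        reference=reference,
    )
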