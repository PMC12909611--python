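"""Residual species associations from the latent-factor loadings.

Each posterior draw of the loading matrix V (species x factors) induces a
residual covariance Omega = V V' and hence a correlation matrix R; because
Omega is invariant to orthogonal rotation of the factors, so is everything
reported here.  A pairwise association is "supported" when the equal-tailed
95% credible interval of R excludes zero — unsupported pairs are left blank
in the rendered matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def residual_correlation_draws(loadings: np.ndarray) -> np.ndarray:
    """Per-draw residual correlation matrices from loading draws.

    ``loadings`` is (draws, species, factors); returns (draws, S, S) with
    R = D^{-1/2} V V' D^{-1/2}, D = diag(V V').  Species with zero loading
    norm in a draw have undefined correlations (NaN) for that draw.
    """
    V = np.asarray(loadings, dtype=float)
    if V.ndim != 3 or V.shape[2] < 1:
        raise ValueError("loadings must be (draws, species, factors) with >= 1 factor")
    omega = np.einsum("dif,djf->dij", V, V)
    diag = np.einsum("dii->di", omega)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = 1.0 / np.sqrt(diag)
        scale[diag <= 0] = np.nan
        R = omega * scale[:, :, None] * scale[:, None, :]
    return R


@dataclass
class AssociationMatrix:
    """Posterior summary of residual correlations with a support screen."""

    species: list[str]
    mean: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame
    supported: pd.DataFrame  # bool: credible interval excludes zero
    level: float
    n_dropped: pd.DataFrame  # undefined draws dropped per pair

    def screened(self) -> pd.DataFrame:
        """Mean correlations with unsupported pairs blanked (NaN)."""
        return self.mean.where(self.supported)

    def to_frame(self) -> pd.DataFrame:
        """Long-format pair table (upper triangle)."""
        rows = []
        S = len(self.species)
        for a in range(S):
            for b in range(a + 1, S):
                sa, sb = self.species[a], self.species[b]
                rows.append(
                    {
                        "species_a": sa, "species_b": sb,
                        "mean": self.mean.iloc[a, b],
                        "lower": self.lower.iloc[a, b],
                        "upper": self.upper.iloc[a, b],
                        "supported": bool(self.supported.iloc[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def screen_associations(
    correlation_draws: np.ndarray,
    species: list[str] | None = None,
    level: float = 0.95,
) -> AssociationMatrix:
    """Screen per-draw correlations into a supported-association matrix.

    Per pair: posterior mean and equal-tailed (1-level) interval; supported
    iff both bounds share a sign.  Draws where a species' correlation is
    undefined (zero loading norm) are dropped pairwise; a species undefined
    in every draw is excluded with a warning.
    """
    R = np.asarray(correlation_draws, dtype=float)
    D, S, _ = R.shape
    need = int(np.ceil(2.0 / (1.0 - level)))
    if D < need:
        raise ValueError(f"need at least {need} draws for a stable {level:.0%} interval")
    species = list(species) if species is not None else [f"sp{j}" for j in range(S)]

    defined = ~np.isnan(np.einsum("dii->di", R))  # (D, S)
    dead = ~defined.any(axis=0)
    if dead.any():
        warnings.warn(
            f"species with all-zero loadings excluded: "
            f"{[species[j] for j in np.nonzero(dead)[0]]}", stacklevel=2,
        )
        keep = ~dead
        R = R[:, keep][:, :, keep]
        species = [s for s, k in zip(species, keep) if k]
        S = len(species)

    alpha = 1.0 - level
    mean = np.nanmean(R, axis=0)
    lower = np.nanquantile(R, alpha / 2, axis=0)
    upper = np.nanquantile(R, 1 - alpha / 2, axis=0)
    supported = (lower > 0) | (upper < 0)
    np.fill_diagonal(mean, 1.0)
    np.fill_diagonal(lower, 1.0)
    np.fill_diagonal(upper, 1.0)
    np.fill_diagonal(supported, True)
    n_dropped = np.isnan(R).sum(axis=0)

    as_df = lambda a, dtype=float: pd.DataFrame(  # noqa: E731
        a.astype(dtype), index=species, columns=species
    )
    return AssociationMatrix(
        species=species,
        mean=as_df(mean),
        lower=as_df(lower),
        upper=as_df(upper),
        supported=as_df(supported, bool),
        level=level,
        n_dropped=as_df(n_dropped, int),
    )


def plot_association_matrix(assoc: AssociationMatrix, path=None):
    """Correlation heat map with unsupported pairs left blank."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = assoc.screened().to_numpy()
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(assoc.species),) * 2)
    masked = np.ma.masked_invalid(data)
    im = ax.imshow(masked, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(assoc.species)), assoc.species, rotation=90)
    ax.set_yticks(range(len(assoc.species)), assoc.species)
    fig.colorbar(im, ax=ax, label="residual correlation")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
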