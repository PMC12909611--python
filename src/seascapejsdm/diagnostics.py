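"""MCMC convergence diagnostics.

Thin wrappers over arviz: rank-normalised split-R-hat and autocorrelation
based effective sample size (Geyer initial-sequence truncation), with
explicit conventions for degenerate all-constant chains.
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np


def _as_chains(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("expected (chains, draws) for a scalar parameter")
    if arr.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    return arr


def gelman_rubin(chains) -> float:
    """Rank-normalised split potential scale reduction factor R-hat.

    Values near 1 (typically < 1.1) indicate the chains agree; identically
    constant chains return exactly 1 by convention.
    """
    arr = _as_chains(chains)
    if np.ptp(arr) == 0:
        return 1.0
    # the rank-normalised estimator can dip below 1 by sampling noise;
    # 1 is the convergence floor
    return max(1.0, float(az.rhat(arr)))


def effective_sample_size(chains) -> float:
    """Autocorrelation-adjusted number of independent draws (bulk ESS).

    Constant chains are degenerate: the total draw count is returned with a
    warning so callers can flag the parameter.
    """
    arr = _as_chains(chains)
    if np.ptp(arr) == 0:
        warnings.warn("constant chains: ESS undefined, returning total draws",
                      stacklevel=2)
        return float(arr.size)
    return float(az.ess(arr))


def summarize_convergence(posterior, max_params: int = 200) -> dict:
    """R-hat and ESS over the coefficient block of a fitted posterior.

    Returns the worst R-hat, the smallest ESS, and per-parameter tables for
    up to ``max_params`` coefficients (row-major over columns x species).
    """
    theta = posterior.theta  # (C, D, p, S)
    C, D, p, S = theta.shape
    flatpar = theta.reshape(C, D, p * S)
    k = min(p * S, max_params)
    rhats = np.array([gelman_rubin(flatpar[:, :, m]) for m in range(k)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        esss = np.array([effective_sample_size(flatpar[:, :, m]) for m in range(k)])
    return {
        "rhat": rhats,
        "ess": esss,
        "max_rhat": float(rhats.max()),
        "min_ess": float(esss.min()),
        "converged": bool(rhats.max() < 1.1),
    }
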