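"""Assembling the analysis count matrix.

MaxN counts (the maximum number of individuals of a species in any single
video frame of a deployment) arrive as a deployments x species table.  Two
preparation steps precede modelling: removing species too rare to support
inference, and checking sampling adequacy with a species accumulation curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class RemovalReport:
    """Outcome of the rarity filter."""

    retained: list[str]
    removed: list[str]
    occurrence: pd.DataFrame  # species x site-year group occurrence counts
    group_sizes: pd.Series
    thresholds: pd.Series  # per-group minimum occurrences to count as common


def filter_rare_species(
    counts: pd.DataFrame,
    site: pd.Series | np.ndarray,
    year: pd.Series | np.ndarray,
    fraction: float = 0.10,
    require_all_groups: bool = False,
    min_occurrences: int | None = None,
) -> tuple[pd.DataFrame, RemovalReport]:
    """Drop species observed in fewer than ``fraction`` of deployments.

    Occurrence is assessed within each site-year group (a species must be
    seen, MaxN > 0, in at least ceiling(fraction x group size) deployments
    of a group to be "common" there; ties at exactly the fraction are
    retained).  By default a species common in at least one group is kept;
    ``require_all_groups`` demands the criterion in every group.  An
    absolute ``min_occurrences`` per group may replace the fraction rule.
    """
    if counts.empty:
        raise ValueError("count matrix is empty")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    site = np.asarray(site)
    year = np.asarray(year)
    if len(site) != len(counts) or len(year) != len(counts):
        raise ValueError("site/year labels must match the deployment rows")

    group = pd.Series(
        [f"{s}:{y}" for s, y in zip(site, year)], index=counts.index, name="group"
    )
    present = counts.gt(0)
    occurrence = present.groupby(group).sum().T  # species x group
    group_sizes = group.value_counts().sort_index()
    occurrence = occurrence[group_sizes.index]
    if min_occurrences is not None:
        thresholds = pd.Series(min_occurrences, index=group_sizes.index, dtype=int)
    else:
        thresholds = np.ceil(fraction * group_sizes).astype(int)
    common = occurrence.ge(thresholds, axis=1)
    keep = common.all(axis=1) if require_all_groups else common.any(axis=1)
    retained = [s for s in counts.columns if keep[s]]
    removed = [s for s in counts.columns if not keep[s]]
    report = RemovalReport(retained, removed, occurrence, group_sizes, thresholds)
    return counts[retained], report


@dataclass
class SpeciesAccumulationCurve:
    """Expected cumulative richness against number of deployments sampled."""

    n_samples: np.ndarray  # 1..N
    mean_richness: np.ndarray  # permutation estimate of E[S_n]
    sd_richness: np.ndarray
    exact_mean: np.ndarray  # closed-form E[S_n]
    final_gradient: float  # new species per additional sample at n = N

    @property
    def total_species(self) -> float:
        return float(self.mean_richness[-1])


def _exact_expected_richness(occupancy: np.ndarray, n_total: int) -> np.ndarray:
    """E[S_n] = sum_j 1 - C(N - F_j, n) / C(N, n) without replacement."""
    n = np.arange(1, n_total + 1)[:, None]
    miss = n_total - occupancy[None, :]
    # log C(miss, n) - log C(N, n); C(miss, n) = 0 when n > miss
    with np.errstate(invalid="ignore"):
        log_ratio = (
            gammaln(miss + 1)
            - gammaln(miss - n + 1)
            + gammaln(n_total - n + 1)
            - gammaln(n_total + 1)
        )
    prob_absent = np.where(n > miss, 0.0, np.exp(log_ratio))
    return (1.0 - prob_absent).sum(axis=1)


def species_accumulation(
    counts: pd.DataFrame, n_permutations: int = 100, seed: int = 0
) -> SpeciesAccumulationCurve:
    """Species accumulation curve by random permutation of deployment order.

    The curve's final gradient — mean richness gained by the last sample —
    is the rate of new species discovery per deployment, the adequacy
    statistic.  The closed-form hypergeometric expectation is returned
    alongside the permutation estimate.
    """
    if len(counts) < 2:
        raise ValueError("species accumulation needs at least two deployments")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    present = counts.to_numpy() > 0
    n_total = present.shape[0]
    richness = np.empty((n_permutations, n_total))
    for p in range(n_permutations):
        order = rng.permutation(n_total)
        richness[p] = np.cumsum(present[order], axis=0).astype(bool).sum(axis=1)
    mean = richness.mean(axis=0)
    sd = richness.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(n_total)
    gradient = float(mean[-1] - mean[-2])
    return SpeciesAccumulationCurve(
        n_samples=np.arange(1, n_total + 1),
        mean_richness=mean,
        sd_richness=sd,
        exact_mean=_exact_expected_richness(present.sum(axis=0), n_total),
        final_gradient=gradient,
    )
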