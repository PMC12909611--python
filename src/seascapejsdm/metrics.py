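"""Seascape covariates from fuzzy substratum probability rasters.

The substratum product consists of one probability surface per class; soft
sediments grade into one another ("fuzzy" boundaries) while rock and cobble
have crisp edges.  Patches are recovered by thresholding each class at its
own cutoff — 0.25 for hard-edged classes, 0.1 for soft ones — after which
the covariates used in the abundance model are computed on the classified
map: distance to the nearest patch boundary, Shannon diversity of the
surrounding substratum mosaic within a fixed radius (clipped to the study
area), slope and aspect from bathymetry, and distance to shore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GridGeometry, Raster

# Depth-stratified design bands (m, positive downward), closed on the left.
DEPTH_STRATUM_EDGES = np.array([0.0, 10.0, 19.0, 30.0, 38.0, 50.0])
DEPTH_STRATUM_MAX = 116.0

HARD_CUTOFF = 0.25
SOFT_CUTOFF = 0.10

DEFAULT_RADII_M = (500.0, 1000.0, 1500.0)


def assign_depth_stratum(depth_m) -> np.ndarray | int:
    """Stratum index 1..6 for a depth in metres (positive downward).

    Bands are 0–9.9, 10–18.9, 19–29.9, 30–37.9, 38–49.9 and 50–116 m,
    closed on the left; depths beyond 116 m are outside the design.
    """
    depth = np.asarray(depth_m, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative (positive downward)")
    if np.any(depth > DEPTH_STRATUM_MAX):
        raise ValueError(f"depth exceeds the {DEPTH_STRATUM_MAX} m design maximum")
    idx = np.searchsorted(DEPTH_STRATUM_EDGES, depth, side="right")
    return idx if depth.ndim else int(idx)


@dataclass
class SubstratumRaster:
    """Aligned per-class probability grids on a shared geometry."""

    classes: list[str]
    probabilities: np.ndarray  # (n_classes, nrow, ncol), values in [0, 1]
    geometry: GridGeometry
    mask: np.ndarray  # in-study (sea) cells

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape[0] != len(self.classes):
            raise ValueError("one probability grid per class required")
        if self.probabilities.shape[1:] != (self.geometry.nrow, self.geometry.ncol):
            raise ValueError("probability grids not aligned to geometry")
        inmask = self.probabilities[:, self.mask]
        if inmask.size and (inmask.min() < 0 or inmask.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PatchMap:
    """Hard classification of the fuzzy product: per-cell label sets,
    dominant class, and the boundary-cell mask."""

    classes: list[str]
    labels: np.ndarray  # (n_classes, nrow, ncol) bool: prob >= cutoff
    dominant: np.ndarray  # (nrow, ncol) int index into classes; -1 if unlabelled
    boundary: np.ndarray  # (nrow, ncol) bool
    cutoffs: dict[str, float]
    geometry: GridGeometry
    mask: np.ndarray


def classify_patches(sub: SubstratumRaster, cutoffs: dict[str, float]) -> PatchMap:
    """Label each cell with every class whose probability meets its cutoff.

    The dominant class is the labelled class of highest probability.
    Raising a class's cutoff can only remove cells from that class.
    """
    missing = [c for c in sub.classes if c not in cutoffs]
    if missing:
        raise ValueError(f"no cutoff supplied for class(es): {missing}")
    for c in sub.classes:
        if not (0.0 < cutoffs[c] < 1.0):
            raise ValueError(f"cutoff for {c} must lie in (0, 1)")

    cut = np.array([cutoffs[c] for c in sub.classes])[:, None, None]
    labels = (sub.probabilities >= cut) & sub.mask[None, :, :]
    masked_probs = np.where(labels, sub.probabilities, -np.inf)
    dominant = np.argmax(masked_probs, axis=0)
    dominant[~labels.any(axis=0)] = -1
    pm = PatchMap(
        classes=list(sub.classes),
        labels=labels,
        dominant=dominant,
        boundary=np.zeros(dominant.shape, dtype=bool),
        cutoffs=dict(cutoffs),
        geometry=sub.geometry,
        mask=sub.mask,
    )
    pm.boundary = patch_boundary_cells(pm)
    return pm


def patch_boundary_cells(patchmap: PatchMap) -> np.ndarray:
    """Boundary mask: a labelled cell is boundary if a 4-neighbour (in the
    study area) has a different dominant class or no label at all, or if the
    cell itself carries two or more labels (a fuzzy overlap zone).

    The shoreline is deliberately not a patch boundary: out-of-mask
    neighbours never trigger the rule.
    """
    dom = patchmap.dominant
    labelled = dom >= 0
    multi = patchmap.labels.sum(axis=0) >= 2
    boundary = labelled & multi

    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb_dom = np.full_like(dom, -2)  # -2: off-grid sentinel, never matches
        nb_mask = np.zeros_like(patchmap.mask)
        src = (slice(max(dr, 0), dom.shape[0] + min(dr, 0)),
               slice(max(dc, 0), dom.shape[1] + min(dc, 0)))
        dst = (slice(max(-dr, 0), dom.shape[0] + min(-dr, 0)),
               slice(max(-dc, 0), dom.shape[1] + min(-dc, 0)))
        nb_dom[dst] = dom[src]
        nb_mask[dst] = patchmap.mask[src]
        differs = nb_mask & (nb_dom != -2) & (nb_dom != dom)
        boundary |= labelled & differs
    return boundary & patchmap.mask


def _as_points(xy) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("locations must be (x, y) pairs")
    return pts


def _nearest_cell_distance(cell_mask: np.ndarray, geometry: GridGeometry, xy) -> np.ndarray:
    """Euclidean distance from each point to the nearest True cell centre."""
    from scipy.spatial import cKDTree

    rows, cols = np.nonzero(cell_mask)
    if rows.size == 0:
        raise ValueError("no eligible cells in raster")
    cx = geometry.x_origin + (cols + 0.5) * geometry.cell_size
    cy = geometry.y_origin + (geometry.nrow - 1 - rows + 0.5) * geometry.cell_size
    tree = cKDTree(np.column_stack([cx, cy]))
    dist, _ = tree.query(_as_points(xy))
    return dist


def distance_to_boundary(patchmap: PatchMap, xy) -> np.ndarray | float:
    """Distance (m) from each location to the nearest boundary-cell centre.

    A location whose own cell is a boundary cell is at distance zero.
    """
    if not patchmap.boundary.any():
        raise ValueError("no patch boundary present")
    pts = _as_points(xy)
    dist = _nearest_cell_distance(patchmap.boundary, patchmap.geometry, pts)
    for i, (x, y) in enumerate(pts):
        r, c = patchmap.geometry.locate(x, y)
        if patchmap.boundary[r, c]:
            dist[i] = 0.0
    return dist if np.asarray(xy).ndim == 2 else float(dist[0])


def shannon_diversity(
    patchmap: PatchMap, xy, radius_m: float, study_mask: np.ndarray | None = None
) -> float:
    """Shannon index H (nats) of dominant-class proportions within a circle.

    Only in-study, labelled cells whose centres fall within ``radius_m`` of
    the location enter the proportions; where the circle spills onto land or
    off the map, only the in-area part counts.
    """
    mask = patchmap.mask if study_mask is None else study_mask
    (x, y), = _as_points(xy)
    geom = patchmap.geometry
    cx, cy = geom.cell_centres()
    within = (cx - x) ** 2 + (cy - y) ** 2 <= radius_m**2
    eligible = within & mask & (patchmap.dominant >= 0)
    n = int(eligible.sum())
    if n == 0:
        raise ValueError("no eligible cells within the diversity radius")
    counts = np.bincount(patchmap.dominant[eligible], minlength=len(patchmap.classes))
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def slope_aspect(bathy: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and downslope compass aspect (degrees) from bathymetry.

    Gradients use Horn's 3x3 weighted differences on the depth surface
    (positive downward); aspect points toward increasing depth, measured
    clockwise from north, and is NaN on flat cells.
    """
    z = bathy.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope/aspect needs at least a 3x3 grid")
    d = bathy.geometry.cell_size
    zp = np.pad(z, 1, mode="edge")
    # rows increase southward: north neighbour is zp[:-2], east is zp[:, 2:]
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * d)  # d(depth)/d(east)
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * d)  # d(depth)/d(north)
    grad = np.hypot(gx, gy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(gx, gy)) % 360.0
    aspect[grad < 1e-12] = np.nan
    return (
        Raster(bathy.geometry, slope, bathy.mask.copy()),
        Raster(bathy.geometry, aspect, bathy.mask.copy()),
    )


def shoreline_cells(mask: np.ndarray) -> np.ndarray:
    """Out-of-mask (land) cells edge-adjacent to at least one in-mask cell."""
    land = ~mask
    adj = np.zeros_like(mask)
    adj[1:, :] |= mask[:-1, :]
    adj[:-1, :] |= mask[1:, :]
    adj[:, 1:] |= mask[:, :-1]
    adj[:, :-1] |= mask[:, 1:]
    return land & adj


def distance_to_shore(xy, mask: np.ndarray, geometry: GridGeometry) -> np.ndarray | float:
    """Distance (m) to the nearest shoreline (land) cell centre."""
    shore = shoreline_cells(mask)
    if not shore.any():
        raise ValueError("mask contains no land/sea transition")
    dist = _nearest_cell_distance(shore, geometry, xy)
    return dist if np.asarray(xy).ndim == 2 else float(dist[0])


def deployment_features(
    deployments: pd.DataFrame,
    sub: SubstratumRaster,
    patchmap: PatchMap,
    bathy: Raster,
    radii_m: tuple[float, ...] = DEFAULT_RADII_M,
) -> pd.DataFrame:
    """Derive the model covariates for every deployment.

    Returns a frame keyed by deployment_id with depth, map-derived dominant
    substratum, boundary distance, Shannon diversity at each radius, shore
    distance, slope, aspect, and depth stratum.
    """
    slope, aspect = slope_aspect(bathy)
    xy = deployments[["x", "y"]].to_numpy()
    rows_cols = [patchmap.geometry.locate(x, y) for x, y in xy]
    dom_idx = np.array([patchmap.dominant[r, c] for r, c in rows_cols])
    feats = pd.DataFrame(
        {
            "deployment_id": deployments["deployment_id"].to_numpy(),
            "site": deployments["site"].to_numpy(),
            "year": deployments["year"].to_numpy(),
            "depth_m": deployments["depth_m"].to_numpy(),
            "substratum": [
                patchmap.classes[i] if i >= 0 else None for i in dom_idx
            ],
            "boundary_dist_m": distance_to_boundary(patchmap, xy),
            "shore_dist_m": distance_to_shore(xy, patchmap.mask, patchmap.geometry),
            "slope_deg": [slope.values[r, c] for r, c in rows_cols],
            "aspect_deg": [aspect.values[r, c] for r, c in rows_cols],
        }
    )
    for radius in radii_m:
        feats[f"H_{int(radius)}"] = [
            shannon_diversity(patchmap, (x, y), radius) for x, y in xy
        ]
    feats["stratum"] = assign_depth_stratum(feats["depth_m"].to_numpy())
    return feats
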