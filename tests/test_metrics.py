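import numpy as np
import pytest

from seascapejsdm.metrics import (
    PatchMap,
    SubstratumRaster,
    assign_depth_stratum,
    classify_patches,
    distance_to_boundary,
    distance_to_shore,
    patch_boundary_cells,
    shannon_diversity,
    slope_aspect,
)
from seascapejsdm.raster import GridGeometry, Raster

CELL = 25.0


def make_sub(probs, mask=None, classes=None):
    probs = np.asarray(probs, dtype=float)
    C, nr, nc = probs.shape
    classes = classes or [f"c{k}" for k in range(C)]
    mask = np.ones((nr, nc), dtype=bool) if mask is None else mask
    return SubstratumRaster(
        classes=classes, probabilities=probs,
        geometry=GridGeometry(0, 0, CELL, nr, nc), mask=mask,
    )


def centre(row, col, nrow):
    return ((col + 0.5) * CELL, (nrow - 1 - row + 0.5) * CELL)


# --- brute-force oracles ----------------------------------------------------


def brute_boundary(pm: PatchMap) -> np.ndarray:
    nr, nc = pm.dominant.shape
    out = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if not pm.mask[r, c] or pm.dominant[r, c] < 0:
                continue
            if pm.labels[:, r, c].sum() >= 2:
                out[r, c] = True
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and pm.mask[rr, cc]:
                    if pm.dominant[rr, cc] != pm.dominant[r, c]:
                        out[r, c] = True
                        break
    return out


def brute_min_distance(cells_mask, geom, x, y):
    best = np.inf
    nr = geom.nrow
    for r in range(nr):
        for c in range(geom.ncol):
            if cells_mask[r, c]:
                cx, cy = (c + 0.5) * CELL, (nr - 1 - r + 0.5) * CELL
                best = min(best, np.hypot(cx - x, cy - y))
    return best


def random_patchmap(seed, nr=25, nc=30, n_classes=3, with_mask=True):
    rng = np.random.default_rng(seed)
    probs = rng.uniform(0, 1, size=(n_classes, nr, nc))
    mask = rng.random((nr, nc)) > 0.1 if with_mask else None
    sub = make_sub(probs, mask=mask)
    cutoffs = {c: 0.4 for c in sub.classes}
    return classify_patches(sub, cutoffs)


# --- classification ---------------------------------------------------------


class TestClassify:
    def test_hard_and_soft_cutoffs(self):
        # rock p=0.30 passes its 0.25 cutoff; mud p=0.05 misses its 0.1
        sub = make_sub(np.array([[[0.30]], [[0.05]]]), classes=["rock", "mud"])
        pm = classify_patches(sub, {"rock": 0.25, "mud": 0.1})
        assert pm.labels[0, 0, 0] and not pm.labels[1, 0, 0]
        assert pm.classes[pm.dominant[0, 0]] == "rock"

    def test_all_below_cutoffs_leaves_cell_unlabelled(self):
        sub = make_sub(np.array([[[0.2]], [[0.05]]]), classes=["rock", "mud"])
        pm = classify_patches(sub, {"rock": 0.25, "mud": 0.1})
        assert pm.dominant[0, 0] == -1
        assert not pm.labels.any()

    def test_overlapping_soft_classes_dominant_by_probability(self):
        sub = make_sub(np.array([[[0.4]], [[0.2]]]), classes=["mud", "sand"])
        pm = classify_patches(sub, {"mud": 0.1, "sand": 0.1})
        assert pm.labels[:, 0, 0].all()
        assert pm.classes[pm.dominant[0, 0]] == "mud"

    def test_missing_cutoff_rejected(self):
        sub = make_sub(np.random.default_rng(0).uniform(size=(2, 3, 3)))
        with pytest.raises(ValueError, match="cutoff"):
            classify_patches(sub, {"c0": 0.1})

    def test_repeatable_and_threshold_monotone(self):
        sub = make_sub(np.random.default_rng(8).uniform(0, 1, size=(3, 20, 20)))
        a = classify_patches(sub, {"c0": 0.3, "c1": 0.4, "c2": 0.4})
        b = classify_patches(sub, {"c0": 0.3, "c1": 0.4, "c2": 0.4})
        np.testing.assert_array_equal(a.dominant, b.dominant)
        # raising one class's cutoff never adds cells to it
        high = classify_patches(sub, {"c0": 0.6, "c1": 0.4, "c2": 0.4})
        assert not (high.labels[0] & ~a.labels[0]).any()


# --- boundaries -------------------------------------------------------------


class TestBoundary:
    def test_uniform_raster_has_no_boundary(self):
        sub = make_sub(np.full((1, 10, 10), 0.9))
        pm = classify_patches(sub, {"c0": 0.25})
        assert not pm.boundary.any()

    def test_two_half_planes_boundary_is_facing_columns(self):
        probs = np.zeros((2, 6, 8))
        probs[0, :, :4] = 0.9
        probs[1, :, 4:] = 0.9
        pm = classify_patches(make_sub(probs), {"c0": 0.25, "c1": 0.25})
        expected = np.zeros((6, 8), dtype=bool)
        expected[:, 3] = expected[:, 4] = True
        np.testing.assert_array_equal(pm.boundary, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        pm = random_patchmap(seed)
        np.testing.assert_array_equal(patch_boundary_cells(pm), brute_boundary(pm))


class TestDistanceToBoundary:
    def test_on_boundary_cell_is_zero(self):
        pm = random_patchmap(3)
        r, c = np.argwhere(pm.boundary)[0]
        assert distance_to_boundary(pm, centre(r, c, pm.geometry.nrow)) == 0.0

    def test_four_cells_from_straight_boundary(self):
        probs = np.zeros((2, 3, 12))
        probs[0, :, :6] = 0.9
        probs[1, :, 6:] = 0.9
        pm = classify_patches(make_sub(probs), {"c0": 0.25, "c1": 0.25})
        # boundary columns are 5 and 6; column 1 is 4 cells from column 5
        assert distance_to_boundary(pm, centre(1, 1, 3)) == pytest.approx(4 * CELL)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_scan(self, seed):
        pm = random_patchmap(seed + 20)
        rng = np.random.default_rng(seed)
        rows, cols = np.nonzero(pm.mask)
        for k in rng.choice(rows.size, size=5, replace=False):
            x, y = centre(rows[k], cols[k], pm.geometry.nrow)
            x += rng.uniform(-10, 10)
            y += rng.uniform(-10, 10)
            got = distance_to_boundary(pm, (x, y))
            want = brute_min_distance(pm.boundary, pm.geometry, x, y)
            if pm.boundary[pm.geometry.locate(x, y)]:
                want = 0.0
            assert got == pytest.approx(want, rel=1e-12)

    def test_no_boundary_raises(self):
        sub = make_sub(np.full((1, 5, 5), 0.9))
        pm = classify_patches(sub, {"c0": 0.25})
        with pytest.raises(ValueError, match="no patch boundary"):
            distance_to_boundary(pm, (60.0, 60.0))


# --- Shannon diversity ------------------------------------------------------


class TestShannon:
    def test_single_class_circle_is_zero(self):
        sub = make_sub(np.full((1, 20, 20), 0.9))
        pm = classify_patches(sub, {"c0": 0.25})
        assert shannon_diversity(pm, (250.0, 250.0), 200.0) == 0.0

    def test_two_equal_classes_ln2(self):
        probs = np.zeros((2, 20, 20))
        probs[0, :, :10] = 0.9
        probs[1, :, 10:] = 0.9
        pm = classify_patches(make_sub(probs), {"c0": 0.25, "c1": 0.25})
        # a huge radius covers the whole (symmetric) raster
        H = shannon_diversity(pm, (250.0, 250.0), 10000.0)
        assert H == pytest.approx(np.log(2))

    def test_four_equal_quadrants_ln4(self):
        probs = np.zeros((4, 20, 20))
        probs[0, :10, :10] = probs[1, :10, 10:] = 0.9
        probs[2, 10:, :10] = probs[3, 10:, 10:] = 0.9
        pm = classify_patches(make_sub(probs), {f"c{k}": 0.25 for k in range(4)})
        H = shannon_diversity(pm, (250.0, 250.0), 10000.0)
        assert H == pytest.approx(np.log(4))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_hand_count(self, seed):
        pm = random_patchmap(seed + 40)
        rng = np.random.default_rng(seed)
        nr = pm.geometry.nrow
        x = rng.uniform(100, 500)
        y = rng.uniform(100, 400)
        radius = rng.uniform(80, 250)
        counts = {}
        for r in range(nr):
            for c in range(pm.geometry.ncol):
                cx, cy = centre(r, c, nr)
                if (cx - x) ** 2 + (cy - y) ** 2 <= radius**2:
                    if pm.mask[r, c] and pm.dominant[r, c] >= 0:
                        counts[pm.dominant[r, c]] = counts.get(pm.dominant[r, c], 0) + 1
        total = sum(counts.values())
        want = -sum(v / total * np.log(v / total) for v in counts.values())
        assert shannon_diversity(pm, (x, y), radius) == pytest.approx(want)

    def test_bounded_by_log_class_count(self):
        for seed in range(5):
            pm = random_patchmap(seed + 60, n_classes=4)
            H = shannon_diversity(pm, (300.0, 250.0), 200.0)
            assert 0.0 <= H <= np.log(4) + 1e-12

    def test_empty_circle_raises(self):
        pm = random_patchmap(2)
        with pytest.raises(ValueError, match="eligible"):
            shannon_diversity(pm, (10.0, 10.0), 1.0)


# --- slope / aspect ---------------------------------------------------------


class TestSlopeAspect:
    def test_planar_ramp(self):
        geom = GridGeometry(0, 0, CELL, 10, 10)
        x = (np.arange(10) + 0.5) * CELL
        depth = np.tile(0.1 * x, (10, 1))
        slope, aspect = slope_aspect(Raster(geom, depth))
        np.testing.assert_allclose(
            slope.values[1:-1, 1:-1], np.degrees(np.arctan(0.1)), rtol=1e-9
        )
        # depth increases eastward: downslope aspect is east (90 deg)
        np.testing.assert_allclose(aspect.values[1:-1, 1:-1], 90.0, atol=1e-9)

    def test_flat_raster_flagged(self):
        geom = GridGeometry(0, 0, CELL, 5, 5)
        slope, aspect = slope_aspect(Raster(geom, np.full((5, 5), 30.0)))
        assert (slope.values == 0).all()
        assert np.isnan(aspect.values).all()

    def test_interior_matches_central_differences(self):
        rng = np.random.default_rng(1)
        geom = GridGeometry(0, 0, CELL, 30, 30)
        from scipy.ndimage import gaussian_filter

        depth = gaussian_filter(rng.normal(size=(30, 30)), 3) * 100
        slope, _ = slope_aspect(Raster(geom, depth))
        gy_c = (depth[:-2, 1:-1] - depth[2:, 1:-1]) / (2 * CELL)
        gx_c = (depth[1:-1, 2:] - depth[1:-1, :-2]) / (2 * CELL)
        want = np.degrees(np.arctan(np.hypot(gx_c, gy_c)))
        np.testing.assert_allclose(slope.values[1:-1, 1:-1], want, atol=0.6)

    def test_too_small_grid(self):
        geom = GridGeometry(0, 0, CELL, 2, 2)
        with pytest.raises(ValueError):
            slope_aspect(Raster(geom, np.zeros((2, 2))))


# --- shore distance ---------------------------------------------------------


class TestShoreDistance:
    def test_adjacent_cell_is_one_cell_away(self):
        mask = np.ones((6, 6), dtype=bool)
        mask[:, 0] = False  # western land strip
        geom = GridGeometry(0, 0, CELL, 6, 6)
        d = distance_to_shore(centre(3, 1, 6), mask, geom)
        assert d == pytest.approx(CELL)

    def test_monotone_moving_seaward(self):
        mask = np.ones((6, 10), dtype=bool)
        mask[:, 0] = False
        geom = GridGeometry(0, 0, CELL, 6, 10)
        dists = [distance_to_shore(centre(3, c, 6), mask, geom) for c in range(1, 10)]
        assert all(b > a for a, b in zip(dists, dists[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((20, 25)) > 0.15
        mask[:, :2] = False
        geom = GridGeometry(0, 0, CELL, 20, 25)
        from seascapejsdm.metrics import shoreline_cells

        shore = shoreline_cells(mask)
        rows, cols = np.nonzero(mask)
        for k in rng.choice(rows.size, size=5, replace=False):
            x, y = centre(rows[k], cols[k], 20)
            got = distance_to_shore((x, y), mask, geom)
            want = brute_min_distance(shore, geom, x, y)
            assert got == pytest.approx(want, rel=1e-12)

    def test_all_sea_mask_raises(self):
        geom = GridGeometry(0, 0, CELL, 5, 5)
        with pytest.raises(ValueError):
            distance_to_shore((60.0, 60.0), np.ones((5, 5), dtype=bool), geom)


# --- depth strata -----------------------------------------------------------


@pytest.mark.parametrize(
    "depth,stratum",
    [(0.0, 1), (9.9, 1), (10.0, 2), (18.9, 2), (19.0, 3), (29.9, 3),
     (30.0, 4), (37.9, 4), (38.0, 5), (49.9, 5), (50.0, 6), (116.0, 6)],
)
def test_depth_stratum_band_edges(depth, stratum):
    assert assign_depth_stratum(depth) == stratum


def test_depth_outside_design_rejected():
    with pytest.raises(ValueError):
        assign_depth_stratum(116.1)
    with pytest.raises(ValueError):
        assign_depth_stratum(-0.5)


from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(derandomize=True, max_examples=60)
@given(
    st.floats(min_value=0.0, max_value=116.0),
    st.floats(min_value=0.0, max_value=116.0),
)
def test_stratum_assignment_is_monotone_in_depth(d1, d2):
    if d1 > d2:
        d1, d2 = d2, d1
    assert 1 <= assign_depth_stratum(d1) <= assign_depth_stratum(d2) <= 6


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.integers(2, 5))
def test_shannon_bounds_on_random_rasters(seed, n_classes):
    """H lies in [0, ln C] and is 0 iff one class occupies the circle."""
    pm = random_patchmap(seed, nr=15, nc=15, n_classes=n_classes)
    try:
        H = shannon_diversity(pm, (190.0, 190.0), 150.0)
    except ValueError:
        return  # no eligible cells in the circle
    assert -1e-12 <= H <= np.log(n_classes) + 1e-12
    cx, cy = pm.geometry.cell_centres()
    inside = (cx - 190.0) ** 2 + (cy - 190.0) ** 2 <= 150.0**2
    present = np.unique(pm.dominant[inside & pm.mask & (pm.dominant >= 0)])
    assert (H == 0.0) == (len(present) == 1)
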