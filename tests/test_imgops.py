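"""Unit and property tests for the classical image operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from lungseg import imgops
from lungseg.imgops import DegenerateImageError

from conftest import disk


# ---------------------------------------------------------------- oracles

def otsu_bruteforce(img):
    """Exhaustive search over the 255 cut points of the 256-bin histogram,
    computing class statistics directly from pixel groups."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    edges = np.histogram_bin_edges(img, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.searchsorted(edges, img.ravel(), side="right") - 1, 0, 255)
    vals = centers[which]
    best, best_t = -1.0, None
    for t in range(255):
        left = vals[which <= t]
        right = vals[which > t]
        if len(left) == 0 or len(right) == 0:
            continue
        w0 = len(left) / len(vals)
        var = w0 * (1 - w0) * (left.mean() - right.mean()) ** 2
        if var > best + 1e-12:
            best, best_t = var, t
    return float(edges[best_t + 1])


def flood_fill_count(binary, connectivity):
    """Brute-force component count by BFS flood fill."""
    binary = np.asarray(binary) > 0
    seen = np.zeros_like(binary, dtype=bool)
    if connectivity == 4:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    count = 0
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    cr, cc = stack.pop()
                    for dr, dc in moves:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return count


# ------------------------------------------------------------------- Otsu

class TestOtsu:
    def test_bimodal_image_splits_the_modes(self):
        img = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)]).reshape(10, 10)
        threshold, binary = imgops.otsu_binarize(img)
        assert 0.1 < threshold < 0.9
        np.testing.assert_array_equal(binary, (img == 0.9).astype(np.uint8))

    @pytest.mark.parametrize("seed", [3, 7, 21])
    def test_threshold_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(64, 64)).astype(np.float64)
        threshold, _ = imgops.otsu_binarize(img)
        assert threshold == pytest.approx(otsu_bruteforce(img), abs=1e-9)

    def test_phantom_body_is_foreground_lungs_are_not(self, clean_slice):
        _, binary = imgops.otsu_binarize(clean_slice.image)
        lungs = clean_slice.mask.astype(bool)
        assert binary[lungs].sum() == 0
        body_interior = imgops.fill_holes(binary).astype(bool) & ~lungs
        assert binary[body_interior].mean() > 0.95

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            imgops.otsu_binarize(np.full((8, 8), 0.5))

    def test_agrees_with_reference_implementation_within_one_bin(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(0)
        img = rng.normal(0.4, 0.2, size=(48, 48))
        threshold, _ = imgops.otsu_binarize(img)
        bin_width = (img.max() - img.min()) / 256
        assert abs(threshold - threshold_otsu(img, nbins=256)) <= bin_width


# ------------------------------------------------------------- clustering

class TestClusteringTree:
    def test_two_valued_image_recovered_exactly_label1_darker(self):
        img = np.where(np.arange(64).reshape(8, 8) < 20, 0.2, 0.8)
        (labels,) = imgops.clustering_tree(img, [2], seed=0)
        np.testing.assert_array_equal(labels == 1, img == 0.2)
        np.testing.assert_array_equal(labels == 2, img == 0.8)

    def test_three_gaussian_mixture_means_recovered(self):
        rng = np.random.default_rng(5)
        means = (0.1, 0.5, 0.9)
        img = np.concatenate(
            [rng.normal(m, 0.02, 400) for m in means]).reshape(40, 30)
        (labels,) = imgops.clustering_tree(img, [3], seed=1)
        for k, m in zip((1, 2, 3), means):
            assert abs(img[labels == k].mean() - m) < 0.05

    def test_returns_one_label_image_per_resolution(self, clean_slice):
        out = imgops.clustering_tree(clean_slice.image, [2, 3], seed=0)
        assert len(out) == 2
        assert set(np.unique(out[0])) == {1, 2}
        assert set(np.unique(out[1])) == {1, 2, 3}

    def test_too_few_distinct_values_raises(self):
        img = np.where(np.arange(16).reshape(4, 4) < 8, 0.0, 1.0)
        with pytest.raises(DegenerateImageError):
            imgops.clustering_tree(img, [3])


# ------------------------------------------------------------- components

class TestConnectedComponents:
    def test_empty_image_has_no_components(self):
        _, n = imgops.connected_components(np.zeros((5, 5), dtype=np.uint8))
        assert n == 0

    def test_two_separated_squares(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[1:4, 1:4] = 1
        img[1:4, 5:8] = 1
        for conn in (4, 8):
            _, n = imgops.connected_components(img, connectivity=conn)
            assert n == 2

    def test_diagonal_pair_depends_on_connectivity(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[1, 1] = img[2, 2] = 1
        assert imgops.connected_components(img, connectivity=4)[1] == 2
        assert imgops.connected_components(img, connectivity=8)[1] == 1

    def test_labels_follow_raster_order(self):
        img = np.zeros((6, 6), dtype=np.uint8)
        img[4, 0] = 1   # later in raster order
        img[0, 4] = 1   # earlier
        labels, n = imgops.connected_components(img)
        assert n == 2
        assert labels[0, 4] == 1 and labels[4, 0] == 2

    @given(img=hnp.arrays(np.uint8, (16, 16), elements=st.integers(0, 1)),
           conn=st.sampled_from([4, 8]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_count_matches_flood_fill_oracle(self, img, conn):
        _, n = imgops.connected_components(img, connectivity=conn)
        assert n == flood_fill_count(img, conn)


# ------------------------------------------------------------- fill holes

class TestFillHoles:
    def test_annulus_becomes_disk(self):
        ring = disk(10) - disk(5, size=31)
        np.testing.assert_array_equal(imgops.fill_holes(ring), disk(10))

    def test_open_c_shape_unchanged(self):
        c = disk(10) - disk(5, size=31)
        c[10:12, 10:] = 0  # cut a channel to the border region
        filled = imgops.fill_holes(c)
        np.testing.assert_array_equal(filled, c)

    def test_filled_area_is_input_plus_hole_area(self):
        blob = disk(14, size=40)
        holes = [disk(2, size=40, center=(14, 14)),
                 disk(3, size=40, center=(24, 20)),
                 disk(2, size=40, center=(18, 26))]
        hole_area = sum(int(h.sum()) for h in holes)
        img = blob.copy()
        for h in holes:
            img[h > 0] = 0
        filled = imgops.fill_holes(img)
        assert int(filled.sum()) == int(img.sum()) + hole_area

    @given(img=hnp.arrays(np.uint8, (16, 16), elements=st.integers(0, 1)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent_and_superset(self, img):
        once = imgops.fill_holes(img)
        assert (once >= img).all()
        np.testing.assert_array_equal(imgops.fill_holes(once), once)


# ------------------------------------------------------------------ canny

class TestCannyEdges:
    def test_blank_image_has_no_edges(self):
        assert imgops.canny_edges(np.zeros((32, 32), dtype=np.uint8)).sum() == 0

    def test_disk_edge_count_near_circumference(self):
        edges = imgops.canny_edges(disk(20))
        assert abs(int(edges.sum()) - 2 * np.pi * 20) < 0.25 * 2 * np.pi * 20

    def test_broken_disk_has_fewer_edge_pixels(self):
        full = disk(20)
        broken = full.copy()
        broken[:25, :] = 0  # keep the lower half: boundary shortens
        assert imgops.canny_edges(broken).sum() < imgops.canny_edges(full).sum()


# ------------------------------------------------------- candidate region

class TestCandidateLungRegion:
    def test_recovers_phantom_lungs(self, clean_slice):
        _, body = imgops.otsu_binarize(clean_slice.image)
        cand = imgops.candidate_lung_region(clean_slice.image, body)
        assert imgops.dice(cand, clean_slice.mask) >= 0.98

    def test_body_without_holes_gives_empty_output(self):
        body = disk(15)
        cand = imgops.candidate_lung_region(body.astype(float), body)
        assert cand.sum() == 0

    def test_single_enclosed_square_recovered_exactly(self):
        body = np.ones((32, 32), dtype=np.uint8)
        body[10:16, 12:20] = 0
        cand = imgops.candidate_lung_region(body.astype(float), body)
        expected = np.zeros_like(body)
        expected[10:16, 12:20] = 1
        np.testing.assert_array_equal(cand, expected)

    def test_small_specks_are_suppressed(self):
        body = np.ones((64, 64), dtype=np.uint8)
        body[30:32, 30:32] = 0  # 4 px speck < 0.1% of 4096
        cand = imgops.candidate_lung_region(body.astype(float), body)
        assert cand.sum() == 0


# ------------------------------------------------------------------- tau2

class TestContourQuality:
    def test_empty_region_scores_zero(self):
        cq = imgops.contour_quality(np.zeros((16, 16), dtype=np.uint8))
        assert cq.a1 == 0 and cq.tau2 == 0.0

    def test_tau2_strictly_increases_with_disk_radius(self):
        taus = [imgops.contour_quality(disk(r)).tau2 for r in (10, 20, 40)]
        assert taus[0] < taus[1] < taus[2]

    def test_closed_phantom_lungs_beat_broken_ones(self, clean_slice, broken_slice):
        taus = {}
        for name, rec in (("closed", clean_slice), ("broken", broken_slice)):
            _, body = imgops.otsu_binarize(rec.image)
            cand = imgops.candidate_lung_region(rec.image, body)
            taus[name] = imgops.contour_quality(cand).tau2
        assert taus["closed"] > taus["broken"]

    def test_a2_never_below_region_area(self):
        region = disk(10) - disk(4, size=31)
        cq = imgops.contour_quality(region)
        assert cq.a2 >= int(region.sum())


# ------------------------------------------------------------------- dice

class TestDice:
    def test_identity_and_disjoint(self):
        a = disk(6)
        assert imgops.dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[0, 0] = 1
        assert imgops.dice(a, b) == 0.0

    def test_shifted_square_worked_example(self):
        x = np.zeros((30, 30), dtype=np.uint8)
        y = np.zeros((30, 30), dtype=np.uint8)
        x[5:15, 5:15] = 1
        y[5:15, 10:20] = 1
        assert imgops.dice(x, y) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert imgops.dice(z, z) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            imgops.dice(np.zeros((3, 3)), np.zeros((4, 4)))

    @given(x=hnp.arrays(np.uint8, (12, 12), elements=st.integers(0, 1)),
           y=hnp.arrays(np.uint8, (12, 12), elements=st.integers(0, 1)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_set_oracle_symmetric_and_bounded(self, x, y):
        xs = {(r, c) for r, c in zip(*np.nonzero(x))}
        ys = {(r, c) for r, c in zip(*np.nonzero(y))}
        expected = (2 * len(xs & ys) / (len(xs) + len(ys))
                    if xs or ys else 1.0)
        d = imgops.dice(x, y)
        assert d == pytest.approx(expected)
        assert d == pytest.approx(imgops.dice(y, x))
        assert 0.0 <= d <= 1.0
        if xs and xs == ys:
            assert d == 1.0
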