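"""Thresholding oracles and the nuclei / cells / cytoplasm segmentation tier."""

from collections import deque

import numpy as np
import pytest

import apicoloc as ap
from apicoloc.images import ApicolocError, ChannelImage, DegenerateInputError, LabelMap
from conftest import label_disk


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------

def brute_otsu_cut(vals: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over integer cuts."""
    vals = vals.astype(np.int64)
    best = None
    for t in range(int(vals.min()), int(vals.max())):
        lo, hi = vals[vals <= t], vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        crit = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if best is None or crit > best[0]:
            best = (crit, t)
    return best[1]


def brute_li_cut(vals: np.ndarray) -> int:
    """Exhaustive cross-entropy minimization over integer cuts."""
    vals = vals.astype(np.float64)
    best = None
    for t in range(int(vals.min()), int(vals.max())):
        lo, hi = vals[vals <= t], vals[vals > t]
        if lo.size == 0 or hi.size == 0 or lo.mean() <= 0 or hi.mean() <= 0:
            continue
        crit = -(lo.sum() * np.log(lo.mean()) + hi.sum() * np.log(hi.mean()))
        if best is None or crit < best[0]:
            best = (crit, t)
    return best[1]


def geodesic_distances(foreground: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """8-connected BFS geodesic distance from a seed within the foreground."""
    dist = np.full(foreground.shape, np.inf)
    q = deque()
    for y, x in zip(*np.nonzero(seed_mask)):
        dist[y, x] = 0
        q.append((y, x))
    h, w = foreground.shape
    while q:
        y, x = q.popleft()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if (0 <= ny < h and 0 <= nx < w and foreground[ny, nx]
                        and dist[ny, nx] == np.inf):
                    dist[ny, nx] = dist[y, x] + 1
                    q.append((ny, nx))
    return dist


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

class TestThresholds:
    def test_two_value_image_classified_exactly(self):
        img = np.where(np.arange(10000).reshape(100, 100) % 2 == 0, 10.0, 200.0)
        for fn in (ap.threshold_otsu2, ap.threshold_min_cross_entropy):
            thr = fn(img)
            assert 10 < thr < 200
            assert np.array_equal(img > thr, img == 200.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_otsu_equals_bruteforce_on_8bit_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        img = ap.generate_bimodal_field(rng.uniform(30, 80), rng.uniform(150, 220),
                                        rng.uniform(5, 30), rng.uniform(0.2, 0.8),
                                        (64, 64), seed)
        v = img.pixels.ravel()
        assert np.array_equal(v > ap.threshold_otsu2(img), v > brute_otsu_cut(v))

    @pytest.mark.parametrize("seed", range(10))
    def test_li_equals_bruteforce_on_8bit_fixtures(self, seed):
        rng = np.random.default_rng(100 + seed)
        img = ap.generate_bimodal_field(rng.uniform(30, 80), rng.uniform(150, 220),
                                        rng.uniform(5, 30), rng.uniform(0.2, 0.8),
                                        (64, 64), 100 + seed)
        v = img.pixels.ravel()
        assert np.array_equal(v > ap.threshold_min_cross_entropy(img),
                              v > brute_li_cut(v))

    def test_bimodal_threshold_lands_between_modes(self):
        img = ap.generate_bimodal_field(50, 200, 10.0, 0.5, (128, 128), seed=42)
        assert 80 < ap.threshold_otsu2(img) < 170

    def test_skimage_crosscheck(self):
        # independent library implementations agree on the binarization
        from skimage.filters import threshold_li, threshold_otsu
        img = ap.generate_bimodal_field(50, 200, 15.0, 0.4, (128, 128), seed=8)
        v = img.pixels
        assert np.array_equal(v > ap.threshold_otsu2(v),
                              v > threshold_otsu(v, nbins=256))
        assert np.array_equal(v > ap.threshold_min_cross_entropy(v),
                              v > threshold_li(v))

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ap.threshold_otsu2(np.full((8, 8), 7.0))
        with pytest.raises(DegenerateInputError):
            ap.threshold_min_cross_entropy(np.full((8, 8), 7.0))

    def test_marker_mask_fixed_and_provenance(self):
        img = ChannelImage(np.arange(100, dtype=float).reshape(10, 10),
                           channel="UMOD")
        mask = ap.marker_mask(img, method="fixed:50")
        assert np.array_equal(mask.mask, img.pixels > 50)
        assert mask.threshold == 50
        assert "UMOD" in mask.provenance


# ---------------------------------------------------------------------------
# Object segmentation
# ---------------------------------------------------------------------------

def _dapi_field(centers, r=8, shape=(128, 128), signal=200.0, background=10.0):
    img = np.full(shape, background)
    gt = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        label_disk(shape, cy, cx, r, gt, i)
    img[gt > 0] = signal
    return ChannelImage(img, channel="DAPI"), gt


class TestSegmentNuclei:
    def test_disjoint_nuclei_counted_and_recovered(self):
        centers = [(30, 30), (30, 90), (90, 30), (90, 90), (60, 60)]
        dapi, gt = _dapi_field(centers)
        labels = ap.segment_nuclei(dapi).labels
        assert labels.max() == len(centers)
        for i in range(1, len(centers) + 1):
            g = gt == i
            matched = np.bincount(labels[g].ravel()).argmax()
            p = labels == matched
            assert (g & p).sum() / (g | p).sum() >= 0.9

    def test_blank_field_gives_zero_labels(self):
        dapi = ChannelImage(np.full((64, 64), 5.0), channel="DAPI")
        assert ap.segment_nuclei(dapi).n_objects == 0

    def test_touching_disks_split_by_watershed(self):
        dapi, _ = _dapi_field([(60, 52), (60, 76)], r=14)
        labels = ap.segment_nuclei(dapi, min_area_px=50, max_area_px=5000)
        assert labels.n_objects == 2

    def test_area_limits_filter_objects(self):
        dapi, _ = _dapi_field([(30, 30)], r=4)  # ~50 px disk
        assert ap.segment_nuclei(dapi, min_area_px=200).n_objects == 0


class TestSegmentCells:
    def test_single_nucleus_in_convex_blob_claims_it_entirely(self):
        er = np.full((64, 64), 5.0)
        er[20:50, 10:60] = 80.0
        nuc = label_disk((64, 64), 35, 35, 5)
        cells = ap.segment_cells(ChannelImage(er, channel="CANX"), LabelMap(nuc))
        expect = (er > 40) | (nuc > 0)
        assert np.array_equal(cells.labels > 0, expect)
        assert cells.n_objects == 1

    def test_two_seeds_partition_blob_along_geodesic_midline(self):
        er = np.full((60, 100), 5.0)
        er[20:40, 10:90] = 80.0
        nuc = np.zeros((60, 100), np.int32)
        nuc[28:32, 24:28] = 1
        nuc[28:32, 72:76] = 2
        cells = ap.segment_cells(ChannelImage(er, channel="CANX"), LabelMap(nuc))
        fg = (er > 40) | (nuc > 0)
        d1 = geodesic_distances(fg, nuc == 1)
        d2 = geodesic_distances(fg, nuc == 2)
        strict = fg & (d1 != d2)
        assert np.array_equal(cells.labels[strict] == 1, d1[strict] < d2[strict])

    def test_nucleus_without_er_signal_becomes_its_own_cell(self):
        er = ChannelImage(np.full((32, 32), 5.0) +
                          np.random.default_rng(0).normal(0, 0.01, (32, 32)),
                          channel="CANX")
        nuc = label_disk((32, 32), 16, 16, 4)
        cells = ap.segment_cells(er, LabelMap(nuc))
        # the cell contains its nucleus; spurious growth is limited to the
        # noise-thresholded foreground
        assert np.all(cells.labels[nuc > 0] == 1)

    def test_segmentation_translation_equivariance(self, small_4i):
        _, stack, _ = small_4i
        from apicoloc.images import translate
        dapi = stack.get(1, "DAPI")
        shifted = dapi.with_pixels(translate(dapi.pixels, 6, -9,
                                             fill=float(dapi.pixels.min())))
        lab = ap.segment_nuclei(dapi).labels
        lab_shifted = ap.segment_nuclei(shifted).labels
        inner = (slice(20, -20), slice(20, -20))
        a = translate(lab.astype(float), 6, -9)[inner]
        b = lab_shifted.astype(float)[inner]
        assert np.array_equal(a > 0, b > 0)


class TestCytoplasmAndBorder:
    def test_cell_equal_to_nucleus_gives_empty_cytoplasm(self):
        nuc = label_disk((32, 32), 16, 16, 5)
        cyto = ap.derive_cytoplasm(LabelMap(nuc.copy()), LabelMap(nuc))
        assert cyto.n_objects == 0 or not (cyto.labels > 0).any()

    def test_disk_in_disk_gives_annulus_of_analytic_area(self):
        cells = label_disk((64, 64), 32, 32, 20)
        nuc = label_disk((64, 64), 32, 32, 8)
        cyto = ap.derive_cytoplasm(LabelMap(cells), LabelMap(nuc))
        assert (cyto.labels > 0).sum() == (cells > 0).sum() - (nuc > 0).sum()

    def test_set_algebra_cytoplasm_union_and_disjointness(self, small_4i):
        _, stack, gt = small_4i
        cells = LabelMap(gt.labels["cells"])
        nuclei = LabelMap(gt.labels["nuclei"])
        cyto = ap.derive_cytoplasm(cells, nuclei)
        assert np.array_equal((cyto.labels > 0) | (nuclei.labels > 0),
                              cells.labels > 0)
        assert not ((cyto.labels > 0) & (nuclei.labels > 0)).any()
        # labelwise identity, not just as sets
        assert np.array_equal(np.where(nuclei.labels > 0, nuclei.labels,
                                       cyto.labels), cells.labels)

    def test_nucleus_outside_cell_rejected(self):
        cells = label_disk((32, 32), 16, 16, 6)
        nuc = label_disk((32, 32), 16, 26, 4)
        with pytest.raises(ApicolocError):
            ap.derive_cytoplasm(LabelMap(cells), LabelMap(nuc))

    def test_interior_objects_unchanged_by_border_filter(self):
        lab = label_disk((64, 64), 32, 32, 10)
        out = ap.filter_border_objects(LabelMap(lab))
        assert np.array_equal(out.labels, lab)

    def test_corner_touching_object_removed(self):
        lab = np.zeros((32, 32), np.int32)
        lab[0, 0] = 1
        lab[15:18, 15:18] = 2
        out = ap.filter_border_objects(LabelMap(lab))
        assert out.n_objects == 1
        assert out.labels[16, 16] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_survivor_count_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        lab = np.zeros((96, 96), np.int32)
        for i in range(1, 25):
            cy, cx = rng.integers(0, 96, 2)
            label_disk((96, 96), cy, cx, int(rng.integers(2, 7)), lab, i)
        lm = LabelMap(lab)
        out = ap.filter_border_objects(lm)
        present = set(np.unique(lab)) - {0}
        border = (set(lab[0, :]) | set(lab[-1, :]) |
                  set(lab[:, 0]) | set(lab[:, -1])) - {0}
        assert out.n_objects == len(present - border)

    def test_border_filter_invariant_under_renumbering(self):
        rng = np.random.default_rng(9)
        lab = np.zeros((48, 48), np.int32)
        for i in range(1, 8):
            cy, cx = rng.integers(4, 44, 2)
            label_disk((48, 48), cy, cx, 3, lab, i)
        perm = np.concatenate([[0], rng.permutation(np.arange(1, lab.max() + 1))])
        out_a = ap.filter_border_objects(LabelMap(lab))
        out_b = ap.filter_border_objects(LabelMap(perm[lab]))
        assert out_a.n_objects == out_b.n_objects
        assert np.array_equal(out_a.labels > 0, out_b.labels > 0)
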