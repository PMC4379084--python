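"""Region-merging segmentation: cost formula oracles and partition recovery."""

import itertools
import math

import numpy as np
import pytest

from phenofuel.phenology_fourier import FourierImage
from phenofuel.raster import GridTransform
from phenofuel.segmentation import (SegParams, SegmentState, enforce_min_size,
                                    merge_cost, segment)

TR = GridTransform(0.0, 0.0, 250.0, -250.0)


def image_from_bands(bands):
    bands = np.asarray(bands, float)
    if bands.ndim == 2:
        bands = np.stack([bands, np.zeros_like(bands), np.zeros_like(bands)])
    mask = np.isfinite(bands).all(axis=0)
    return FourierImage(A0=bands[0], A1=bands[1], A2=bands[2],
                        valid_mask=mask, transform=TR)


# ---------------------------------------------------------------------------
# independent brute-force reimplementation of the merging rule
# ---------------------------------------------------------------------------

def brute_force_segment(bands, valid, params):
    """Same mutual-best-fitting rule, but every quantity recomputed from raw
    pixel lists at every step (no incremental statistics)."""
    nb, rows, cols = bands.shape
    weights = params.band_weights or (1.0,) * nb
    regions = {}
    for r in range(rows):
        for c in range(cols):
            if valid[r, c]:
                regions[r * cols + c + 1] = {(r, c)}

    def adjacent(p1, p2):
        return any(abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1
                   for a in p1 for b in p2)

    def perimeter(pix):
        return sum(4 - sum((r + dr, c + dc) in pix
                           for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)))
                   for r, c in pix)

    def h_color(pix):
        n = len(pix)
        out = 0.0
        for b, w in enumerate(weights):
            v = np.array([bands[b, r, c] for r, c in pix])
            out += w * n * v.std()
        return out

    def h_shape(pix, kind):
        n = len(pix)
        l = perimeter(pix)
        if kind == "cmpct":
            return n * l / math.sqrt(n)
        rs = [p[0] for p in pix]; cs = [p[1] for p in pix]
        bb = 2 * ((max(rs) - min(rs) + 1) + (max(cs) - min(cs) + 1))
        return n * l / bb

    def cost(p1, p2):
        m = p1 | p2
        d_color = h_color(m) - h_color(p1) - h_color(p2)
        c = (1 - params.shape_weight) * d_color
        if params.shape_weight > 0:
            d_cm = h_shape(m, "cmpct") - h_shape(p1, "cmpct") - h_shape(p2, "cmpct")
            d_sm = h_shape(m, "smooth") - h_shape(p1, "smooth") - h_shape(p2, "smooth")
            c += params.shape_weight * (params.compactness_weight * d_cm
                                        + (1 - params.compactness_weight) * d_sm)
        return max(c, 0.0)

    scale2 = params.scale ** 2
    while True:
        merged = False
        for sid in sorted(regions):
            if sid not in regions:
                continue
            nbrs = [o for o in sorted(regions) if o != sid
                    and adjacent(regions[sid], regions[o])]
            if not nbrs:
                continue
            costs = [(cost(regions[sid], regions[o]), o) for o in nbrs]
            best_cost, best = min(costs)
            if best_cost >= scale2:
                continue
            back = [o for o in sorted(regions) if o != best
                    and adjacent(regions[best], regions[o])]
            back_cost, back_best = min((cost(regions[best], regions[o]), o)
                                       for o in back)
            if back_best != sid:
                continue
            a, b = min(sid, best), max(sid, best)
            regions[a] = regions[a] | regions[b]
            del regions[b]
            merged = True
        if not merged:
            break
    labels = np.zeros((rows, cols), int)
    for i, sid in enumerate(sorted(regions), start=1):
        for r, c in regions[sid]:
            labels[r, c] = i
    return labels


def partitions_equal(a, b):
    """Same partition up to relabelling (nodata stays 0 in both)."""
    mapping = {}
    for x, y in zip(a.ravel(), b.ravel()):
        if (x == 0) != (y == 0):
            return False
        if x == 0:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


# ---------------------------------------------------------------------------

class TestMergeCost:
    def _two_pixel_segments(self, v1, v2):
        s1 = SegmentState(1, (v1,), 0, 0)
        s2 = SegmentState(2, (v2,), 0, 1)
        s1.neighbors[2] = 1
        s2.neighbors[1] = 1
        return s1, s2

    def test_identical_values_zero_color_cost(self):
        s1, s2 = self._two_pixel_segments(0.7, 0.7)
        p = SegParams(scale=1.0, shape_weight=0.0)
        assert merge_cost(s1, s2, p) == 0.0

    def test_hand_evaluated_unit_contrast(self):
        # merged: n=2, sd=0.5 -> delta = 2*0.5 - 0 - 0 = 1.0
        s1, s2 = self._two_pixel_segments(0.0, 1.0)
        p = SegParams(scale=1.0, shape_weight=0.0, band_weights=(1.0,))
        assert merge_cost(s1, s2, p) == pytest.approx(1.0, abs=1e-12)

    def test_non_adjacent_pair_rejected(self):
        s1 = SegmentState(1, (0.0,), 0, 0)
        s2 = SegmentState(2, (0.0,), 0, 5)
        with pytest.raises(ValueError, match="not adjacent"):
            merge_cost(s1, s2, SegParams(scale=1.0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_running_sums_match_raw_pixel_recomputation(self, seed):
        # audit mode recomputes segment statistics from member pixel lists
        rng = np.random.default_rng(seed)
        img = image_from_bands(rng.uniform(0, 1, size=(3, 12, 12)))
        segment(img, SegParams(scale=0.8, shape_weight=0.2, min_pixels=1),
                audit=True)


class TestSegment:
    def test_constant_image_single_segment(self):
        # with colour-only heterogeneity every merge is free, so any scale works
        img = image_from_bands(np.full((8, 8), 0.5))
        for scale in (0.1, 1.0, 100.0):
            labels = segment(img, SegParams(scale=scale, shape_weight=0.0,
                                            min_pixels=1))
            assert len(labels.table) == 1
        # with the default shape weight the scale must absorb the shape cost
        labels = segment(img, SegParams(scale=50.0, min_pixels=1))
        assert len(labels.table) == 1

    def test_high_contrast_blocks_stay_separate(self):
        band = np.zeros((6, 10))
        band[:, 5:] = 1000.0
        labels = segment(image_from_bands(band),
                         SegParams(scale=1.0, shape_weight=0.0, min_pixels=1))
        assert len(labels.table) == 2
        assert len(np.unique(labels.labels[:, :5])) == 1
        assert len(np.unique(labels.labels[:, 5:])) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle_on_tiny_images(self, seed):
        rng = np.random.default_rng(seed)
        band = rng.choice([0.0, 0.3, 1.0], size=(3, 3))
        img = image_from_bands(band)
        params = SegParams(scale=0.7, shape_weight=0.3, compactness_weight=0.6,
                           min_pixels=1)
        got = segment(img, params).labels
        want = brute_force_segment(img.bands(), img.valid_mask, params)
        assert partitions_equal(got, want)

    def test_segmentation_is_deterministic(self):
        rng = np.random.default_rng(5)
        img = image_from_bands(rng.uniform(0, 1, size=(10, 10)))
        p = SegParams(scale=0.5, min_pixels=1)
        a = segment(img, p)
        b = segment(img, p)
        assert (a.labels == b.labels).all()

    def test_pixel_and_sum_conservation(self):
        rng = np.random.default_rng(8)
        bands = rng.uniform(0, 1, size=(3, 15, 15))
        img = image_from_bands(bands)
        labels = segment(img, SegParams(scale=0.6, min_pixels=1))
        t = labels.table
        assert t["n_pixels"].sum() == 15 * 15
        for i, name in enumerate(["mean_A0", "mean_A1", "mean_A2"]):
            assert (t[name] * t["n_pixels"]).sum() == pytest.approx(
                bands[i].sum(), abs=1e-9)

    def test_larger_scale_never_more_segments(self):
        rng = np.random.default_rng(2)
        img = image_from_bands(rng.uniform(0, 1, size=(12, 12)))
        counts = [len(segment(img, SegParams(scale=s, min_pixels=1)).table)
                  for s in (0.1, 0.3, 0.6, 1.0, 3.0)]
        assert counts == sorted(counts, reverse=True)

    def test_zero_noise_blocks_recovered_over_scale_range(
            self, zero_noise_class_map, zero_noise_fourier):
        for scale in (0.5, 2.0, 5.0):
            labels = segment(zero_noise_fourier,
                             SegParams(scale=scale, shape_weight=0.0, min_pixels=1))
            assert partitions_equal(labels.labels, zero_noise_class_map.values)

    def test_segments_never_span_nodata_gaps(self):
        band = np.full((5, 7), 0.4)
        band[:, 3] = np.nan                        # nodata column splits the image
        labels = segment(image_from_bands(band),
                         SegParams(scale=10.0, shape_weight=0.0, min_pixels=1))
        assert (labels.labels[:, 3] == 0).all()
        assert len(labels.table) == 2


class TestEnforceMinSize:
    def test_idempotent_when_all_units_large_enough(self):
        band = np.zeros((6, 10))
        band[:, 5:] = 1000.0
        img = image_from_bands(band)
        params = SegParams(scale=1.0, shape_weight=0.0, min_pixels=10)
        labels = segment(img, params)
        again = enforce_min_size(labels, img, params)
        assert (again.labels == labels.labels).all()

    def test_small_unit_absorbed_by_closest_color(self):
        # middle column is its own unit, closer in value to the left block
        band = np.zeros((4, 9))
        band[:, 4] = 0.1
        band[:, 5:] = 1000.0
        img = image_from_bands(band)
        params = SegParams(scale=0.01, shape_weight=0.0, min_pixels=8)
        raw = segment(img, params, apply_min_size=False)
        assert len(raw.table) == 3
        cleaned = enforce_min_size(raw, img, params)
        assert len(cleaned.table) == 2
        assert cleaned.labels[0, 4] == cleaned.labels[0, 0]

    def test_result_is_a_fixed_point(self):
        rng = np.random.default_rng(4)
        img = image_from_bands(rng.uniform(0, 1, size=(10, 10)))
        params = SegParams(scale=0.3, shape_weight=0.0, min_pixels=5)
        cleaned = segment(img, params)
        assert (cleaned.table["n_pixels"] >= 5).all()
        again = enforce_min_size(cleaned, img, params)
        assert (again.labels == cleaned.labels).all()
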