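"""UPGMA clustering of phenological units: hand oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

import phenofuel.synthetic_scene as scene
from conftest import fourier_of
from phenofuel.segmentation import SegParams, segment
from phenofuel.unit_clustering import (ClassAssignment, UnitFeatureTable,
                                       cut_to_classes, split_largest_spatial,
                                       unit_features, upgma_linkage)


def features_from_matrix(x, centroids=None):
    x = np.asarray(x, float)
    n = len(x)
    if centroids is None:
        centroids = np.zeros((n, 2))
    return UnitFeatureTable(table=pd.DataFrame({
        "unit_id": np.arange(1, n + 1),
        "n_pixels": 10, "area_km2": 0.625,
        "mean_A0": x[:, 0], "mean_A1": x[:, 1], "mean_A2": x[:, 2],
        "centroid_x": centroids[:, 0], "centroid_y": centroids[:, 1],
    }))


def brute_force_cophenetic(x):
    """Recursive average-linkage (all pairwise point distances) oracle."""
    x = np.asarray(x, float)
    n = len(x)
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))

    def dist(a, b):
        return np.mean([np.linalg.norm(x[i] - x[j])
                        for i in clusters[a] for j in clusters[b]])

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(((dist(a, b), a, b) for i, a in enumerate(keys)
                    for b in keys[i + 1:]))
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


class TestUnitFeatures:
    def test_two_pixel_mean_and_area(self, zero_noise_fourier):
        img = zero_noise_fourier
        labels = segment(img, SegParams(scale=1.0, shape_weight=0.0, min_pixels=1))
        feats = unit_features(labels, img)
        # 250 m pixels -> 0.0625 km2 each
        assert np.allclose(feats.table["area_km2"],
                           feats.table["n_pixels"] * 0.0625)

    def test_zero_noise_unit_means_equal_class_truth(self, zero_noise_config,
                                                     zero_noise_class_map,
                                                     zero_noise_fourier):
        labels = segment(zero_noise_fourier,
                         SegParams(scale=1.0, shape_weight=0.0, min_pixels=1))
        feats = unit_features(labels, zero_noise_fourier)
        truth = {(s.base_level, s.amp1, s.amp2)
                 for s in zero_noise_config.class_specs}
        got = {tuple(np.round(row, 9)) for row in feats.matrix()}
        assert got == {tuple(np.round(t, 9)) for t in truth}

    def test_misregistered_inputs_rejected(self, zero_noise_fourier):
        labels = segment(zero_noise_fourier,
                         SegParams(scale=1.0, shape_weight=0.0, min_pixels=1))
        labels.labels = labels.labels[:10, :10]
        with pytest.raises(ValueError, match="co-registered"):
            unit_features(labels, zero_noise_fourier)


class TestUpgma:
    def test_two_units_merge_at_their_distance(self):
        feats = features_from_matrix([[0, 0, 0], [3, 4, 0]])
        tree = upgma_linkage(feats)
        assert tree.linkage.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(5.0)

    def test_three_unit_hand_computed_merge_sequence(self):
        # pairwise distances: d(A,B)=1, d(A,C)=5, d(B,C)=4
        # UPGMA: merge (A,B) at 1, then average d(AB,C) = (5+4)/2 = 4.5
        feats = features_from_matrix([[0, 0, 0], [1, 0, 0], [5, 0, 0]])
        tree = upgma_linkage(feats)
        assert tree.heights == pytest.approx([1.0, 4.5])

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        feats = features_from_matrix(rng.uniform(0, 1, size=(12, 3)))
        h = upgma_linkage(feats).heights
        assert (np.diff(h) >= -1e-12).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cophenetic_matches_recursive_oracle(self, seed):
        x = np.random.default_rng(seed).uniform(0, 1, size=(6, 3))
        tree = upgma_linkage(features_from_matrix(x))
        assert np.allclose(tree.cophenetic(), brute_force_cophenetic(x), atol=1e-9)

    def test_non_finite_features_rejected(self):
        feats = features_from_matrix([[0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError, match="finite"):
            upgma_linkage(feats)

    def test_newick_export_has_all_leaves(self):
        feats = features_from_matrix(np.random.default_rng(1).uniform(size=(5, 3)))
        nwk = upgma_linkage(feats).to_newick()
        assert nwk.endswith(";")
        assert all(f"u{u}" in nwk for u in range(1, 6))


class TestCutToClasses:
    def test_extreme_cuts(self):
        feats = features_from_matrix(np.random.default_rng(2).uniform(size=(7, 3)))
        tree = upgma_linkage(feats)
        allk = cut_to_classes(tree, 7, feats)
        assert allk.assignment["pfc_label"].nunique() == 7
        one = cut_to_classes(tree, 1, feats)
        assert one.assignment["pfc_label"].nunique() == 1

    def test_hand_computed_two_cluster_cut(self):
        feats = features_from_matrix([[0, 0, 0], [1, 0, 0], [5, 0, 0]])
        tree = upgma_linkage(feats)
        cut = cut_to_classes(tree, 2, feats)
        labels = cut.assignment.set_index("unit_id")["pfc_label"]
        assert labels[1] == labels[2] != labels[3]

    def test_labels_ordered_by_descending_seasonality(self):
        # two tight clusters with distinct mean_A1; higher A1 must be PFC1
        x = [[0.3, 0.05, 0.0], [0.31, 0.06, 0.0],
             [0.9, 0.40, 0.1], [0.91, 0.41, 0.1]]
        feats = features_from_matrix(x)
        cut = cut_to_classes(upgma_linkage(feats), 2, feats)
        labels = cut.assignment.set_index("unit_id")["pfc_label"]
        assert labels[3] == labels[4] == "PFC1"
        assert labels[1] == labels[2] == "PFC2"

    def test_cut_nesting_property(self):
        feats = features_from_matrix(
            np.random.default_rng(3).uniform(size=(10, 3)))
        tree = upgma_linkage(feats)
        for k in range(2, 10):
            fine = cut_to_classes(tree, k, feats).assignment["pfc_label"]
            coarse = cut_to_classes(tree, k - 1, feats).assignment["pfc_label"]
            # every fine cluster is wholly inside one coarse cluster
            df = pd.DataFrame({"fine": fine, "coarse": coarse})
            assert (df.groupby("fine")["coarse"].nunique() == 1).all()

    def test_k_out_of_range(self):
        feats = features_from_matrix(np.random.default_rng(4).uniform(size=(4, 3)))
        tree = upgma_linkage(feats)
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_to_classes(tree, k, feats)


class TestSplitLargestSpatial:
    def _assignment(self, n, label="PFC1"):
        return ClassAssignment(assignment=pd.DataFrame({
            "unit_id": np.arange(1, n + 1), "pfc_label": label}))

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(0)
        left = rng.normal([0, 0], 1.0, size=(6, 2))
        right = rng.normal([100, 0], 1.0, size=(6, 2))
        cents = np.vstack([left, right])
        feats = features_from_matrix(np.tile([0.5, 0.1, 0.0], (12, 1)), cents)
        out = split_largest_spatial(self._assignment(12), feats)
        labels = out.assignment["pfc_label"].to_numpy()
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
        assert set(labels) == {"PFC1a", "PFC1b"}

    def test_identical_centroids_degenerate(self):
        feats = features_from_matrix(np.tile([0.5, 0.1, 0.0], (4, 1)),
                                     np.zeros((4, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            split_largest_spatial(self._assignment(4), feats)

    def test_single_unit_class_cannot_split(self):
        feats = features_from_matrix([[0.5, 0.1, 0.0]], np.zeros((1, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            split_largest_spatial(self._assignment(1), feats)

    def test_split_is_deterministic(self):
        rng = np.random.default_rng(5)
        cents = rng.uniform(0, 100, size=(10, 2))
        feats = features_from_matrix(np.tile([0.5, 0.1, 0.0], (10, 1)), cents)
        a = split_largest_spatial(self._assignment(10), feats, seed=3)
        b = split_largest_spatial(self._assignment(10), feats, seed=3)
        assert a.assignment.equals(b.assignment)


class TestEndToEndRecovery:
    def test_four_class_scene_recovered_by_clustering(self, zero_noise_config,
                                                      zero_noise_class_map,
                                                      zero_noise_fourier):
        from sklearn.metrics import adjusted_rand_score
        labels = segment(zero_noise_fourier,
                         SegParams(scale=2.0, shape_weight=0.0, min_pixels=25))
        feats = unit_features(labels, zero_noise_fourier)
        cut = cut_to_classes(upgma_linkage(feats), 4, feats)
        per_pixel = cut.labels_for(labels.labels.ravel())
        ari = adjusted_rand_score(zero_noise_class_map.values.ravel(), per_pixel)
        assert ari >= 0.95
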