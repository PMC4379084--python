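"""Clustering of phenological units into phenological fuel classes (PFCs).

Units are summarised by the mean Fourier components (A0, A1, A2) of their
member pixels and clustered by UPGMA (average linkage) on Euclidean
distances.  Cutting the dendrogram at k clusters yields the fuel classes,
labelled PFC1..PFCk in order of decreasing mean first-harmonic amplitude —
the most seasonal (and empirically most fire-prone) class first.

Features are deliberately not standardised before computing distances; a
``standardize`` flag enables z-scoring for scenes whose components live on
very different scales.

An optional spatial split of the largest class into two subgroups (labelled
``a``/``b``) is provided as an automatic surrogate for expert-knowledge
subdivision: 2-means on unit centroids, with the more coastal subgroup
(smaller mean distance to the convex-hull boundary of the scene's unit
centroids) taking the ``a`` suffix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from shapely.geometry import MultiPoint, Point
from sklearn.cluster import KMeans

from .phenology_fourier import FourierImage
from .segmentation import SegmentLabelMap

__all__ = ["UnitFeatureTable", "LinkageTree", "ClassAssignment",
           "unit_features", "upgma_linkage", "cut_to_classes",
           "split_largest_spatial"]

FEATURE_COLS = ["mean_A0", "mean_A1", "mean_A2"]


@dataclass
class UnitFeatureTable:
    """One row per phenological unit: Fourier means, size and centroid."""

    table: pd.DataFrame   # unit_id, n_pixels, area_km2, mean_A0/A1/A2, centroid_x/y

    def __len__(self):
        return len(self.table)

    def matrix(self, standardize: bool = False) -> np.ndarray:
        x = self.table[FEATURE_COLS].to_numpy(float)
        if standardize:
            sd = x.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            x = (x - x.mean(axis=0)) / sd
        return x


@dataclass
class LinkageTree:
    """UPGMA merge sequence in scipy linkage form."""

    linkage: np.ndarray      # (n-1, 4) scipy linkage matrix
    unit_ids: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix in unit_ids order."""
        from scipy.spatial.distance import squareform
        d = hierarchy.cophenet(self.linkage)
        return squareform(d)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        ids = self.unit_ids

        def rec(node) -> str:
            if node.is_leaf():
                return f"u{ids[node.id]}"
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


@dataclass
class ClassAssignment:
    """Mapping of units to fuel-class labels."""

    assignment: pd.DataFrame   # unit_id, pfc_label

    def labels_for(self, unit_ids) -> np.ndarray:
        lut = dict(zip(self.assignment["unit_id"], self.assignment["pfc_label"]))
        return np.array([lut[u] for u in unit_ids])

    def class_table(self, features: UnitFeatureTable) -> pd.DataFrame:
        df = features.table.merge(self.assignment, on="unit_id")
        return (df.groupby("pfc_label")
                  .agg(n_units=("unit_id", "size"),
                       n_pixels=("n_pixels", "sum"),
                       area_km2=("area_km2", "sum"),
                       mean_A0=("mean_A0", "mean"),
                       mean_A1=("mean_A1", "mean"),
                       mean_A2=("mean_A2", "mean"))
                  .reset_index())


def unit_features(labels: SegmentLabelMap, fourier: FourierImage) -> UnitFeatureTable:
    """Per-unit means of the Fourier components plus size and centroid."""
    if labels.labels.shape != fourier.valid_mask.shape:
        raise ValueError("label map and Fourier image are not co-registered")
    tr = fourier.transform
    px_area_km2 = abs(tr.dx * tr.dy) / 1e6
    rows = []
    for uid in labels.unit_ids:
        m = labels.labels == uid
        n = int(m.sum())
        if n == 0 or not np.isfinite(fourier.A0[m]).all():
            raise ValueError(f"unit {uid} has no valid pixels")
        rr, cc = np.nonzero(m)
        cx, cy = tr.xy(rr, cc)
        rows.append({
            "unit_id": int(uid), "n_pixels": n, "area_km2": n * px_area_km2,
            "mean_A0": float(fourier.A0[m].mean()),
            "mean_A1": float(fourier.A1[m].mean()),
            "mean_A2": float(fourier.A2[m].mean()),
            "centroid_x": float(np.mean(cx)), "centroid_y": float(np.mean(cy)),
        })
    return UnitFeatureTable(table=pd.DataFrame(rows))


def upgma_linkage(features: UnitFeatureTable, standardize: bool = False) -> LinkageTree:
    """Average-linkage hierarchical clustering on Euclidean feature distances."""
    x = features.matrix(standardize=standardize)
    if len(x) < 2:
        raise ValueError("need at least 2 units to cluster")
    if not np.isfinite(x).all():
        raise ValueError("non-finite unit features")
    z = hierarchy.linkage(x, method="average", metric="euclidean")
    return LinkageTree(linkage=z, unit_ids=features.table["unit_id"].to_numpy())


def cut_to_classes(tree: LinkageTree, k: int,
                   features: UnitFeatureTable | None = None) -> ClassAssignment:
    """Cut the dendrogram into k classes, labelled by decreasing seasonality.

    The k clusters are those obtained by removing the k−1 highest merges.
    Labels PFC1..PFCk are ordered by descending mean of the member units'
    mean_A1 (most seasonal first); without a feature table, cluster order
    falls back to scipy's flat-cluster numbering.
    """
    n = len(tree.unit_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    flat = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    order_key = {}
    if features is not None:
        a1 = features.table.set_index("unit_id").loc[tree.unit_ids, "mean_A1"].to_numpy()
        for c in np.unique(flat):
            order_key[c] = -float(a1[flat == c].mean())
    else:
        order_key = {c: c for c in np.unique(flat)}
    ordered = sorted(np.unique(flat), key=lambda c: (order_key[c], c))
    relabel = {c: f"PFC{i + 1}" for i, c in enumerate(ordered)}
    return ClassAssignment(assignment=pd.DataFrame({
        "unit_id": tree.unit_ids,
        "pfc_label": [relabel[c] for c in flat],
    }))


def split_largest_spatial(assignment: ClassAssignment, features: UnitFeatureTable,
                          seed: int = 0) -> ClassAssignment:
    """Split the largest class (by area) into two spatial subgroups.

    2-means on unit centroids (50 restarts, fixed seed).  The subgroup whose
    centroids lie on average closer to the convex-hull boundary of all unit
    centroids — a coastal-proximity proxy — takes suffix ``a``; the other
    ``b``.  Other classes are untouched.
    """
    df = features.table.merge(assignment.assignment, on="unit_id")
    areas = df.groupby("pfc_label")["area_km2"].sum()
    target = areas.idxmax()
    sub = df[df["pfc_label"] == target]
    if len(sub) < 2:
        raise ValueError(f"largest class {target} has fewer than 2 units; cannot split")
    pts = sub[["centroid_x", "centroid_y"]].to_numpy(float)
    if np.allclose(pts, pts[0]):
        raise ValueError("all unit centroids identical; spatial split is degenerate")

    km = KMeans(n_clusters=2, n_init=50, random_state=seed).fit(pts)
    hull = MultiPoint([tuple(p) for p in df[["centroid_x", "centroid_y"]]
                       .to_numpy(float)]).convex_hull
    boundary = hull.boundary if hull.geom_type == "Polygon" else hull
    edge_dist = np.array([boundary.distance(Point(*p)) for p in pts])
    mean_edge = [edge_dist[km.labels_ == g].mean() for g in (0, 1)]
    suffix_of_group = {int(np.argmin(mean_edge)): "a", int(np.argmax(mean_edge)): "b"}
    if mean_edge[0] == mean_edge[1]:
        suffix_of_group = {0: "a", 1: "b"}

    new = assignment.assignment.copy()
    sub_labels = dict(zip(sub["unit_id"], km.labels_))
    new["pfc_label"] = [
        f"{lab}{suffix_of_group[sub_labels[uid]]}" if lab == target else lab
        for uid, lab in zip(new["unit_id"], new["pfc_label"])
    ]
    return ClassAssignment(assignment=new)
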