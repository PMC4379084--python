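"""Bottom-up region merging of the Fourier feature image into phenological units.

Implements multiresolution segmentation in the Fractal Net Evolution style:
every valid pixel starts as its own region and adjacent regions are merged
pairwise while the increase in weighted colour + shape heterogeneity stays
below the squared scale parameter.  The colour term is the band-weighted
increase in n-weighted population standard deviation; the shape term blends a
compactness criterion (perimeter / sqrt(area), area-weighted) with a
smoothness criterion (perimeter / bounding-box perimeter, area-weighted).

Merging uses local mutual best fitting with a deterministic ascending-id
visiting order: in each pass a region merges with its cheapest neighbour only
if the choice is mutual and the cost is below scale²; ties break toward the
lower neighbour id.  Passes repeat until no merge occurs.  A final cleanup
absorbs regions below the minimum pixel count into their most similar
neighbour (colour cost only).

Region statistics (per-band sum and sum of squares, perimeter, bounding box,
shared-edge counts) are maintained incrementally so each merge is O(number of
neighbours).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology_fourier import FourierImage
from .raster import GridTransform, Raster

__all__ = ["SegParams", "SegmentState", "SegmentLabelMap",
           "merge_cost", "segment", "enforce_min_size"]


@dataclass(frozen=True)
class SegParams:
    """Segmentation parameters.

    Defaults are the operational values used for 250 m seasonal Fourier
    imagery (scale 500, shape 0.2, compactness 0.8, minimum unit size 25
    pixels); on small synthetic scenes the scale parameter must be chosen
    relative to the scene's band contrast.
    """

    scale: float = 500.0
    shape_weight: float = 0.2
    compactness_weight: float = 0.8
    band_weights: tuple[float, ...] | None = None   # None = equal weights
    min_pixels: int = 25
    connectivity: int = 4

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        for name in ("shape_weight", "compactness_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.band_weights is not None:
            if any(w < 0 for w in self.band_weights) or not any(self.band_weights):
                raise ValueError("band_weights must be nonnegative, not all zero")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")


class SegmentState:
    """Running statistics of one region of the merge graph."""

    __slots__ = ("id", "n", "sums", "sumsq", "perimeter",
                 "rmin", "rmax", "cmin", "cmax", "neighbors", "members")

    def __init__(self, sid: int, values: tuple[float, ...], row: int, col: int):
        nb = len(values)
        self.id = sid
        self.n = 1
        self.sums = [float(v) for v in values]
        self.sumsq = [float(v) * float(v) for v in values]
        self.perimeter = 4          # exposed pixel-edge count, 4-connectivity
        self.rmin = self.rmax = row
        self.cmin = self.cmax = col
        self.neighbors: dict[int, int] = {}   # neighbour id -> shared edge count
        self.members: list[int] | None = None  # only tracked in audit mode

    # -- derived quantities -------------------------------------------------
    def sd(self, b: int) -> float:
        mu = self.sums[b] / self.n
        var = self.sumsq[b] / self.n - mu * mu
        return math.sqrt(var) if var > 0 else 0.0

    def bbox_perimeter(self) -> float:
        return 2.0 * ((self.rmax - self.rmin + 1) + (self.cmax - self.cmin + 1))


def _weighted_color(n: int, sums: list[float], sumsq: list[float],
                    weights: tuple[float, ...]) -> float:
    h = 0.0
    for b, w in enumerate(weights):
        if w == 0.0:
            continue
        mu = sums[b] / n
        var = sumsq[b] / n - mu * mu
        h += w * n * (math.sqrt(var) if var > 0 else 0.0)
    return h


def merge_cost(s1: SegmentState, s2: SegmentState, params: SegParams) -> float:
    """Heterogeneity increase of merging two adjacent regions (clamped at 0)."""
    shared = s1.neighbors.get(s2.id)
    if shared is None:
        raise ValueError(f"segments {s1.id} and {s2.id} are not adjacent")

    nb = len(s1.sums)
    weights = params.band_weights or (1.0,) * nb
    n_m = s1.n + s2.n
    sums_m = [s1.sums[b] + s2.sums[b] for b in range(nb)]
    sumsq_m = [s1.sumsq[b] + s2.sumsq[b] for b in range(nb)]
    d_color = (_weighted_color(n_m, sums_m, sumsq_m, weights)
               - _weighted_color(s1.n, s1.sums, s1.sumsq, weights)
               - _weighted_color(s2.n, s2.sums, s2.sumsq, weights))

    cost = (1.0 - params.shape_weight) * d_color
    if params.shape_weight > 0.0:
        l_m = s1.perimeter + s2.perimeter - 2 * shared
        b_m = 2.0 * ((max(s1.rmax, s2.rmax) - min(s1.rmin, s2.rmin) + 1)
                     + (max(s1.cmax, s2.cmax) - min(s1.cmin, s2.cmin) + 1))
        d_cmpct = (n_m * l_m / math.sqrt(n_m)
                   - s1.n * s1.perimeter / math.sqrt(s1.n)
                   - s2.n * s2.perimeter / math.sqrt(s2.n))
        d_smooth = (n_m * l_m / b_m
                    - s1.n * s1.perimeter / s1.bbox_perimeter()
                    - s2.n * s2.perimeter / s2.bbox_perimeter())
        d_shape = (params.compactness_weight * d_cmpct
                   + (1.0 - params.compactness_weight) * d_smooth)
        cost += params.shape_weight * d_shape
    return max(cost, 0.0)


@dataclass
class SegmentLabelMap:
    """Integer raster of unit ids (0 = nodata) with a per-unit summary table."""

    labels: np.ndarray
    transform: GridTransform
    crs: str = ""
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def unit_ids(self) -> np.ndarray:
        return np.asarray(sorted(np.unique(self.labels[self.labels > 0])))

    def to_raster(self) -> Raster:
        return Raster(values=self.labels.astype(np.int32), transform=self.transform,
                      crs=self.crs, nodata=0)


# ---------------------------------------------------------------------------
# graph construction and merging
# ---------------------------------------------------------------------------

def _build_graph(bands: np.ndarray, valid: np.ndarray, connectivity: int,
                 audit: bool) -> dict[int, SegmentState]:
    nbands, rows, cols = bands.shape
    segs: dict[int, SegmentState] = {}
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            sid = r * cols + c + 1
            seg = SegmentState(sid, tuple(bands[:, r, c]), r, c)
            if audit:
                seg.members = [r * cols + c]
            segs[sid] = seg
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            sid = r * cols + c + 1
            if c + 1 < cols and valid[r, c + 1]:
                _add_edge(segs, sid, sid + 1, 1)
            if r + 1 < rows and valid[r + 1, c]:
                _add_edge(segs, sid, sid + cols, 1)
            if connectivity == 8:
                if r + 1 < rows and c + 1 < cols and valid[r + 1, c + 1]:
                    _add_edge(segs, sid, sid + cols + 1, 0)
                if r + 1 < rows and c - 1 >= 0 and valid[r + 1, c - 1]:
                    _add_edge(segs, sid, sid + cols - 1, 0)
    return segs


def _add_edge(segs, a: int, b: int, shared: int) -> None:
    segs[a].neighbors[b] = segs[a].neighbors.get(b, 0) + shared
    segs[b].neighbors[a] = segs[b].neighbors.get(a, 0) + shared


def _merge_pair(segs: dict[int, SegmentState], a: int, b: int) -> int:
    """Merge region b into region a (a < b); returns the surviving id."""
    s, t = segs[a], segs[b]
    shared = s.neighbors[b]
    s.n += t.n
    for k in range(len(s.sums)):
        s.sums[k] += t.sums[k]
        s.sumsq[k] += t.sumsq[k]
    s.perimeter = s.perimeter + t.perimeter - 2 * shared
    s.rmin = min(s.rmin, t.rmin); s.rmax = max(s.rmax, t.rmax)
    s.cmin = min(s.cmin, t.cmin); s.cmax = max(s.cmax, t.cmax)
    if s.members is not None:
        s.members.extend(t.members)
    del s.neighbors[b]
    for nbr, cnt in t.neighbors.items():
        if nbr == a:
            continue
        nseg = segs[nbr]
        del nseg.neighbors[b]
        nseg.neighbors[a] = nseg.neighbors.get(a, 0) + cnt
        s.neighbors[nbr] = s.neighbors.get(nbr, 0) + cnt
    del segs[b]
    return a


def _best_neighbor(segs, seg: SegmentState, params: SegParams) -> tuple[int, float] | None:
    best_id, best_cost = -1, math.inf
    for nbr in sorted(seg.neighbors):
        c = merge_cost(seg, segs[nbr], params)
        if c < best_cost:
            best_id, best_cost = nbr, c
    return (best_id, best_cost) if best_id >= 0 else None


def _audit_check(seg: SegmentState, bands: np.ndarray) -> None:
    cols = bands.shape[2]
    rr = np.array(seg.members) // cols
    cc = np.array(seg.members) % cols
    vals = bands[:, rr, cc]
    assert seg.n == len(seg.members)
    for b in range(bands.shape[0]):
        if not math.isclose(seg.sums[b], float(vals[b].sum()), rel_tol=1e-9, abs_tol=1e-9):
            raise AssertionError(f"running sum mismatch in segment {seg.id}, band {b}")
        if not math.isclose(seg.sumsq[b], float((vals[b] ** 2).sum()),
                            rel_tol=1e-9, abs_tol=1e-9):
            raise AssertionError(f"running sumsq mismatch in segment {seg.id}, band {b}")


def _merge_until_stable(segs: dict[int, SegmentState], params: SegParams,
                        bands: np.ndarray | None = None,
                        threshold: float | None = None) -> dict[int, int]:
    """Local mutual-best-fitting passes; returns the absorbed->survivor map."""
    scale2 = params.scale ** 2 if threshold is None else threshold
    parent: dict[int, int] = {}
    n_merges = 0
    while True:
        merged_any = False
        for sid in sorted(segs):
            seg = segs.get(sid)
            if seg is None or not seg.neighbors:
                continue
            best = _best_neighbor(segs, seg, params)
            if best is None:
                continue
            nbr, cost = best
            if cost >= scale2:
                continue
            back = _best_neighbor(segs, segs[nbr], params)
            if back is None or back[0] != sid:
                continue
            a, b = (sid, nbr) if sid < nbr else (nbr, sid)
            _merge_pair(segs, a, b)
            parent[b] = a
            merged_any = True
            n_merges += 1
            if bands is not None and segs[a].members is not None and n_merges % 100 == 0:
                _audit_check(segs[a], bands)
        if not merged_any:
            return parent


def _resolve(parent: dict[int, int], labels0: np.ndarray) -> np.ndarray:
    def find(i: int) -> int:
        root = i
        while root in parent:
            root = parent[root]
        while i in parent:
            parent[i], i = root, parent[i]
        return root

    out = labels0.copy()
    flat = out.ravel()
    for idx in np.nonzero(flat)[0]:
        flat[idx] = find(int(flat[idx]))
    return out


def _finalize(labels_raw: np.ndarray, image: FourierImage) -> SegmentLabelMap:
    """Relabel contiguously from 1 and build the per-unit summary table."""
    ids = np.unique(labels_raw[labels_raw > 0])
    remap = {int(old): i + 1 for i, old in enumerate(ids)}
    labels = np.zeros_like(labels_raw, dtype=np.int32)
    for old, new in remap.items():
        labels[labels_raw == old] = new

    tr = image.transform
    px_area_km2 = abs(tr.dx * tr.dy) / 1e6
    rows = []
    for uid in range(1, len(ids) + 1):
        m = labels == uid
        rows.append({
            "unit_id": uid,
            "n_pixels": int(m.sum()),
            "area_km2": float(m.sum() * px_area_km2),
            "mean_A0": float(image.A0[m].mean()),
            "mean_A1": float(image.A1[m].mean()),
            "mean_A2": float(image.A2[m].mean()),
        })
    return SegmentLabelMap(labels=labels, transform=tr, crs=image.crs,
                           table=pd.DataFrame(rows))


def segment(image: FourierImage, params: SegParams, *,
            apply_min_size: bool = True, audit: bool = False) -> SegmentLabelMap:
    """Partition the Fourier image into phenologically homogeneous units."""
    valid = image.valid_mask
    if not valid.any():
        raise ValueError("no valid pixels to segment")
    bands = image.bands()
    segs = _build_graph(bands, valid, params.connectivity, audit)

    rows, cols = valid.shape
    labels0 = np.zeros((rows, cols), dtype=np.int64)
    rr, cc = np.nonzero(valid)
    labels0[rr, cc] = rr * cols + cc + 1

    parent = _merge_until_stable(segs, params, bands=bands if audit else None)
    labels_raw = _resolve(parent, labels0)
    out = _finalize(labels_raw, image)
    if apply_min_size and params.min_pixels > 1:
        out = enforce_min_size(out, image, params)
    return out


def enforce_min_size(labels: SegmentLabelMap, image: FourierImage,
                     params: SegParams) -> SegmentLabelMap:
    """Absorb undersized units into their most colour-similar neighbour.

    Repeatedly merges the smallest unit below ``min_pixels`` (ties toward the
    lower id) into the adjacent unit with minimal colour heterogeneity
    increase; shape is ignored.  Idempotent once all units reach the minimum
    size (or a single unit remains).
    """
    segs = _rebuild_graph(labels, image)
    color_params = SegParams(scale=params.scale, shape_weight=0.0,
                             compactness_weight=params.compactness_weight,
                             band_weights=params.band_weights,
                             min_pixels=params.min_pixels,
                             connectivity=params.connectivity)
    parent: dict[int, int] = {}
    while len(segs) > 1:
        small = [s for s in segs.values() if s.n < params.min_pixels]
        if not small:
            break
        seg = min(small, key=lambda s: (s.n, s.id))
        best = _best_neighbor(segs, seg, color_params)
        if best is None:
            break
        a, b = (seg.id, best[0]) if seg.id < best[0] else (best[0], seg.id)
        _merge_pair(segs, a, b)
        parent[b] = a
    labels_raw = _resolve(parent, labels.labels.astype(np.int64))
    return _finalize(labels_raw, image)


def _rebuild_graph(labels: SegmentLabelMap, image: FourierImage
                   ) -> dict[int, SegmentState]:
    """Reconstruct region statistics from a label raster and band image."""
    lab = labels.labels
    bands = image.bands()
    rows, cols = lab.shape
    segs: dict[int, SegmentState] = {}
    for r in range(rows):
        for c in range(cols):
            sid = int(lab[r, c])
            if sid == 0:
                continue
            if sid not in segs:
                seg = SegmentState(sid, tuple(bands[:, r, c]), r, c)
                segs[sid] = seg
            else:
                seg = segs[sid]
                seg.n += 1
                for b in range(bands.shape[0]):
                    v = float(bands[b, r, c])
                    seg.sums[b] += v
                    seg.sumsq[b] += v * v
                seg.rmin = min(seg.rmin, r); seg.rmax = max(seg.rmax, r)
                seg.cmin = min(seg.cmin, c); seg.cmax = max(seg.cmax, c)
                seg.perimeter += 4
    for r in range(rows):
        for c in range(cols):
            sid = int(lab[r, c])
            if sid == 0:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= rows or c2 >= cols:
                    continue
                sid2 = int(lab[r2, c2])
                if sid2 == 0:
                    continue
                if sid2 == sid:
                    segs[sid].perimeter -= 2
                else:
                    _add_edge(segs, sid, sid2, 1)
    return segs
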