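"""Fire-proneness statistics for phenological zones.

The central quantity is the selection ratio

    σ_c = (n_c / N) / (a_c / A),

the share of ignitions falling in zone c divided by the zone's share of the
landscape.  σ ≈ 1 means ignitions hit the zone at random-expectation rate,
σ > 1 fire-proneness, σ < 1 fire-avoidance.

Three randomization tests accompany it:

* a multinomial Monte Carlo test of each zone's σ against the null of
  area-proportional ignition (fires reallocated to zones with probabilities
  equal to relative areas);
* a one-way permutational ANOVA of per-unit σ across classes (F from the
  classical between/within sums of squares, p by permuting unit labels,
  one-tailed);
* a-posteriori pairwise permutation F tests between classes.

Two-tailed Monte Carlo p-values use the doubled smaller tail with add-one
continuity; a ``tail="single"`` flag reports the smaller tail undoubled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster
from .segmentation import SegmentLabelMap
from .synthetic_scene import IgnitionSet

__all__ = ["SelectivityResult", "AnovaResult", "count_fires_per_zone",
           "selection_ratios", "monte_carlo_sigma_test", "permutation_anova",
           "pairwise_permutation_f"]


@dataclass
class SelectivityResult:
    """Per-zone fire counts, selection ratios and Monte Carlo p-values."""

    table: pd.DataFrame        # zone, n_fires, area, rel_area, rel_fires, sigma, p_value
    n_total: int
    n_reps: int
    seed: int | None
    null_summary: pd.DataFrame  # zone, null_mean_sigma, null_sd_sigma


@dataclass
class AnovaResult:
    F_observed: float
    p_value: float
    n_permutations: int
    seed: int | None
    group_means: pd.Series


def count_fires_per_zone(zones: SegmentLabelMap | Raster, fires: IgnitionSet,
                         crs: str | None = None) -> tuple[pd.Series, int]:
    """Count ignition points per zone id by point-in-pixel overlay.

    Points are mapped to pixels through the inverse geotransform with the
    half-open interval convention, so a point exactly on a shared edge is
    assigned deterministically.  Points outside the extent or on nodata are
    excluded; their number is returned alongside the counts.
    """
    if isinstance(zones, SegmentLabelMap):
        lab, tr, zcrs = zones.labels, zones.transform, zones.crs
    else:
        lab, tr, zcrs = zones.values, zones.transform, zones.crs
    if crs is not None and zcrs and crs != zcrs:
        raise ValueError(f"CRS mismatch: fires {crs!r} vs zones {zcrs!r}")

    row, col = tr.rowcol(fires.x, fires.y)
    rows, cols = lab.shape
    inside = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
    zone = np.zeros(len(fires.x), dtype=lab.dtype)
    zone[inside] = lab[row[inside], col[inside]]
    keep = inside & (zone != 0)

    ids = sorted(int(z) for z in np.unique(lab[lab != 0]))
    counts = pd.Series(0, index=ids, dtype=int, name="n_fires")
    got = pd.Series(zone[keep]).value_counts()
    for z, c in got.items():
        counts.loc[int(z)] = int(c)
    return counts, int((~keep).sum())


def selection_ratios(counts, areas) -> np.ndarray:
    """σ_c = (n_c/N) / (a_c/A) per zone; zones with no fires get σ = 0."""
    n = np.asarray(counts, dtype=float)
    a = np.asarray(areas, dtype=float)
    if n.shape != a.shape:
        raise ValueError("counts and areas must align")
    if (a <= 0).any():
        raise ValueError("all zone areas must be > 0")
    N, A = n.sum(), a.sum()
    if N <= 0:
        raise ValueError("no fires assigned to any zone")
    return (n / N) / (a / A)


def _two_tailed_p(null: np.ndarray, observed: np.ndarray, n_reps: int,
                  tail: str) -> np.ndarray:
    """Monte Carlo p per column: doubled smaller tail, add-one rule."""
    lo = (null <= observed).sum(axis=0) + 1
    hi = (null >= observed).sum(axis=0) + 1
    smaller = np.minimum(lo, hi)
    if tail == "single":
        return smaller / (n_reps + 1)
    return np.minimum(1.0, 2.0 * smaller / (n_reps + 1))


def monte_carlo_sigma_test(counts, areas, n_reps: int = 9999,
                           seed: int | None = None,
                           tail: str = "double") -> SelectivityResult:
    """Test each zone's selection ratio against area-proportional ignition.

    Each replicate reallocates all N fires to the zones by a multinomial
    draw with probabilities a_c/A and recomputes σ*; two-tailed p-values
    compare the observed σ with the 9999-style null sample.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if tail not in ("double", "single"):
        raise ValueError("tail must be 'double' or 'single'")
    n = np.asarray(counts, dtype=float)
    a = np.asarray(areas, dtype=float)
    sigma = selection_ratios(n, a)
    N = int(n.sum())
    p_area = a / a.sum()

    rng = np.random.default_rng(seed)
    null_counts = rng.multinomial(N, p_area, size=n_reps).astype(float)
    null_sigma = (null_counts / N) / p_area
    pvals = _two_tailed_p(null_sigma, sigma, n_reps, tail)

    idx = counts.index if isinstance(counts, pd.Series) else np.arange(len(n))
    table = pd.DataFrame({
        "zone": idx, "n_fires": n.astype(int), "area": a,
        "rel_area": p_area, "rel_fires": n / N,
        "sigma": sigma, "p_value": pvals,
    })
    null_summary = pd.DataFrame({
        "zone": idx,
        "null_mean_sigma": null_sigma.mean(axis=0),
        "null_sd_sigma": null_sigma.std(axis=0, ddof=1),
    })
    return SelectivityResult(table=table, n_total=N, n_reps=n_reps, seed=seed,
                             null_summary=null_summary)


def _anova_f(values: np.ndarray, group_codes: np.ndarray, g: int) -> float:
    n = values.size
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for c in range(g):
        v = values[group_codes == c]
        ssb += v.size * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    if ssw == 0.0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (g - 1)) / (ssw / (n - g))


def permutation_anova(sigma_per_unit, class_labels, n_perms: int = 9999,
                      seed: int | None = None) -> AnovaResult:
    """One-way permutational ANOVA of per-unit selection ratios.

    F is the classical between/within mean-square ratio; the p-value is
    one-tailed, the fraction of label permutations with F* ≥ F (add-one
    rule).  With zero within-group variance and non-zero between-group
    variance, F is infinite and p is the minimum attainable 1/(n_perms+1).
    """
    values = np.asarray(sigma_per_unit, dtype=float)
    labels = np.asarray(class_labels)
    if values.size != labels.size:
        raise ValueError("sigma values and class labels must align")
    groups, codes = np.unique(labels, return_inverse=True)
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 classes")
    if values.size - g < 1:
        raise ValueError("no within-group degrees of freedom")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")

    f_obs = _anova_f(values, codes, g)
    rng = np.random.default_rng(seed)

    # Permuting values against fixed labels == permuting labels.
    n = values.size
    counts = np.bincount(codes, minlength=g).astype(float)
    perm_vals = np.empty((n_perms, n))
    for i in range(n_perms):
        perm_vals[i] = values[rng.permutation(n)]
    onehot = np.eye(g)[codes]                       # (n, g)
    gsum = perm_vals @ onehot                       # (n_perms, g)
    gmean = gsum / counts
    grand = perm_vals.mean(axis=1, keepdims=True)
    ssb = (counts * (gmean - grand) ** 2).sum(axis=1)
    sst = ((perm_vals - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb / (g - 1)) / (ssw / (n - g))
    f_perm = np.where(ssw == 0, np.where(ssb > 0, np.inf, 0.0), f_perm)

    if np.isinf(f_obs):
        p = 1.0 / (n_perms + 1)
    else:
        p = ((f_perm >= f_obs).sum() + 1) / (n_perms + 1)
    means = pd.Series({grp: values[codes == c].mean()
                       for c, grp in enumerate(groups)})
    return AnovaResult(F_observed=float(f_obs), p_value=float(p),
                       n_permutations=n_perms, seed=seed, group_means=means)


def pairwise_permutation_f(sigma_per_unit, class_labels, n_perms: int = 9999,
                           seed: int | None = None) -> pd.DataFrame:
    """A-posteriori pairwise permutation F tests between all class pairs.

    Each unordered pair gets its own permutation stream spawned from the
    caller's seed.  No multiplicity adjustment is applied.  Pairs with fewer
    than 3 units in total are flagged not-testable (NaN F and p).
    """
    values = np.asarray(sigma_per_unit, dtype=float)
    labels = np.asarray(class_labels)
    groups = np.unique(labels)
    streams = np.random.SeedSequence(seed).spawn(len(groups) * len(groups))
    rows = []
    k = 0
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            child_seed = int(streams[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            m = (labels == ga) | (labels == gb)
            if m.sum() < 3:
                rows.append({"class_a": ga, "class_b": gb,
                             "F": np.nan, "p_value": np.nan, "testable": False})
                continue
            res = permutation_anova(values[m], labels[m], n_perms=n_perms,
                                    seed=child_seed)
            rows.append({"class_a": ga, "class_b": gb,
                         "F": res.F_observed, "p_value": res.p_value,
                         "testable": True})
    return pd.DataFrame(rows)
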