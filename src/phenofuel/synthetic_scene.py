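"""Synthetic phenological scenes with known ground truth.

Generates NDVI raster time-series, categorical covariate maps and fire
ignition points for landscapes built from a small number of phenological
classes.  Each class has a known mean NDVI level (the truth for the Fourier
additive term A0), known 1-cycle and 2-cycle harmonic amplitudes (truths for
A1 and A2), and a known fire multiplier that fixes its true selection ratio,
so every downstream stage of the pipeline can be tested against an exact
oracle.

The seasonal signal is a sum of cosines at exactly the first two discrete
Fourier frequencies of the composite grid, so harmonic-amplitude recovery is
exact at zero noise.  Inter-annual variability is a per-year additive scalar:
averaging years into a mean profile absorbs it into A0, mirroring how a
multi-year mean profile is built from real imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .raster import GridTransform, Raster

__all__ = [
    "PhenoClassSpec",
    "SceneConfig",
    "ClassMap",
    "IgnitionSet",
    "generate_class_map",
    "generate_ndvi_stack",
    "generate_covariate_map",
    "generate_ignitions",
    "true_selection_ratios",
    "default_scene_config",
]


@dataclass(frozen=True)
class PhenoClassSpec:
    """Ground-truth phenology and fire behaviour of one landscape class."""

    class_id: int
    base_level: float          # NDVI units; truth for A0
    amp1: float                # NDVI units; truth for A1 (1 cycle / season)
    amp2: float                # NDVI units; truth for A2 (2 cycles / season)
    phase1: float = 0.0        # radians
    phase2: float = 0.0
    fire_multiplier: float = 1.0
    covariate_label: str = "unlabelled"

    def __post_init__(self):
        if not 0.0 <= self.base_level <= 1.0:
            raise ValueError(f"class {self.class_id}: base_level must be in [0, 1]")
        if self.amp1 < 0 or self.amp2 < 0:
            raise ValueError(f"class {self.class_id}: amplitudes must be >= 0")
        if self.fire_multiplier < 0:
            raise ValueError(f"class {self.class_id}: fire_multiplier must be >= 0")
        if not -1.0 <= self.base_level - (self.amp1 + self.amp2) \
                or not self.base_level + (self.amp1 + self.amp2) <= 1.0:
            raise ValueError(
                f"class {self.class_id}: base_level +/- (amp1+amp2) leaves [-1, 1]"
            )


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, signal realism, and RNG seeds.

    Defaults mirror the structure of a 13-year archive of 11 seasonal 16-day
    NDVI composites at 250 m resolution.
    """

    n_rows: int
    n_cols: int
    class_specs: tuple[PhenoClassSpec, ...]
    n_years: int = 13
    n_composites: int = 11
    noise_sd: float = 0.02
    year_effect_sd: float = 0.01
    patch_seed: int = 0
    fire_seed: int = 1
    n_fires: int = 2000
    pixel_size: float = 250.0
    layout: str = "blocks"       # "blocks" or "seeded"
    covariate_noise: float = 0.0  # fraction of pixels given a random other label
    origin_x: float = 500000.0
    origin_y: float = 4500000.0
    crs: str = "EPSG:32632"

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_composites < 5:
            raise ValueError("n_composites must be >= 5 to resolve two harmonics")
        if self.noise_sd < 0 or self.year_effect_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.class_specs:
            raise ValueError("at least one class spec is required")
        ids = [s.class_id for s in self.class_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("class ids must be unique")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(self.origin_x, self.origin_y, self.pixel_size, -self.pixel_size)

    def spec_for(self, class_id: int) -> PhenoClassSpec:
        for s in self.class_specs:
            if s.class_id == class_id:
                return s
        raise KeyError(f"no class spec with id {class_id}")

    def to_yaml(self, path) -> None:
        doc = {
            "scene": {
                k: getattr(self, k)
                for k in (
                    "n_rows", "n_cols", "n_years", "n_composites", "noise_sd",
                    "year_effect_sd", "patch_seed", "fire_seed", "n_fires",
                    "pixel_size", "layout", "covariate_noise",
                    "origin_x", "origin_y", "crs",
                )
            },
            "classes": [
                {
                    "class_id": s.class_id, "base_level": s.base_level,
                    "amp1": s.amp1, "amp2": s.amp2,
                    "phase1": s.phase1, "phase2": s.phase2,
                    "fire_multiplier": s.fire_multiplier,
                    "covariate_label": s.covariate_label,
                }
                for s in self.class_specs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        specs = tuple(PhenoClassSpec(**c) for c in doc["classes"])
        return cls(class_specs=specs, **doc["scene"])


class ClassMap(Raster):
    """Integer raster of ground-truth class ids."""


@dataclass
class IgnitionSet:
    """Fire ignition points in map coordinates."""

    x: np.ndarray
    y: np.ndarray
    date: np.ndarray | None = None

    def __len__(self):
        return len(self.x)

    def to_csv(self, path) -> None:
        date = self.date if self.date is not None else [""] * len(self.x)
        pd.DataFrame({"x": self.x, "y": self.y, "date": date}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IgnitionSet":
        df = pd.read_csv(path)
        if not {"x", "y"}.issubset(df.columns):
            raise ValueError(f"{path}: ignition CSV needs 'x' and 'y' columns")
        date = df["date"].to_numpy() if "date" in df.columns and len(df) else None
        return cls(x=df["x"].to_numpy(float), y=df["y"].to_numpy(float), date=date)


def default_scene_config(n_rows: int = 60, n_cols: int = 60, **overrides) -> SceneConfig:
    """Four-class scene emulating the observed gradient of fuel classes.

    Productivity (A0) rises and seasonality (A1, A2) falls from the most to
    the least fire-prone class, and fire multipliers decrease in step, the
    qualitative pattern seen across real phenological fuel classes.
    """
    specs = (
        PhenoClassSpec(1, base_level=0.35, amp1=0.20, amp2=0.080,
                       fire_multiplier=2.0, covariate_label="arable"),
        PhenoClassSpec(2, base_level=0.45, amp1=0.15, amp2=0.060,
                       fire_multiplier=1.4, covariate_label="heterogeneous_agricultural"),
        PhenoClassSpec(3, base_level=0.55, amp1=0.08, amp2=0.030,
                       fire_multiplier=0.7, covariate_label="grasslands_pastures"),
        PhenoClassSpec(4, base_level=0.65, amp1=0.04, amp2=0.015,
                       fire_multiplier=0.3, covariate_label="forests"),
    )
    cfg = SceneConfig(n_rows=n_rows, n_cols=n_cols, class_specs=specs)
    return replace(cfg, **overrides) if overrides else cfg


def _block_layout(n_rows: int, n_cols: int, k: int) -> np.ndarray:
    """Partition the grid into k rectangular blocks on a near-square tile grid."""
    tile_rows = max(d for d in range(1, int(math.isqrt(k)) + 1) if k % d == 0)
    tile_cols = k // tile_rows
    row_edges = np.linspace(0, n_rows, tile_rows + 1).astype(int)
    col_edges = np.linspace(0, n_cols, tile_cols + 1).astype(int)
    out = np.zeros((n_rows, n_cols), dtype=np.int32)
    idx = 0
    for i in range(tile_rows):
        for j in range(tile_cols):
            out[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = idx
            idx += 1
    return out


def _seeded_layout(n_rows: int, n_cols: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Voronoi growth from k random seed pixels; cells are contiguous."""
    flat = rng.choice(n_rows * n_cols, size=k, replace=False)
    sr, sc = np.divmod(flat, n_cols)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    return np.argmin(d2, axis=-1).astype(np.int32)


def generate_class_map(config: SceneConfig) -> ClassMap:
    """Deterministic map of spatially contiguous class patches."""
    k = len(config.class_specs)
    if k > config.n_rows * config.n_cols:
        raise ValueError("more classes than pixels: some class would have zero area")
    if config.layout == "blocks":
        idx = _block_layout(config.n_rows, config.n_cols, k)
    elif config.layout == "seeded":
        rng = np.random.default_rng(np.random.SeedSequence([config.patch_seed, 0]))
        idx = _seeded_layout(config.n_rows, config.n_cols, k, rng)
    else:
        raise ValueError(f"unknown layout {config.layout!r}")
    ids = np.array([s.class_id for s in config.class_specs], dtype=np.int32)
    counts = np.bincount(idx.ravel(), minlength=k)
    for pos, c in enumerate(counts):
        if c == 0:
            raise ValueError(f"class {ids[pos]} received zero area")
    return ClassMap(values=ids[idx], transform=config.transform, crs=config.crs, nodata=0)


def generate_ndvi_stack(class_map: ClassMap, config: SceneConfig) -> np.ndarray:
    """Seasonal NDVI series, shape (n_years, n_composites, n_rows, n_cols).

    value(y, t, pixel of class c) =
        base_c + amp1_c cos(2πt/N − φ1_c) + amp2_c cos(4πt/N − φ2_c)
        + yearEffect_y + ε,   ε ~ N(0, noise_sd),
    clipped to [-1, 1].  Deterministic given patch_seed.
    """
    ids_present = np.unique(class_map.values[class_map.mask()])
    known = {s.class_id for s in config.class_specs}
    missing = set(ids_present.tolist()) - known
    if missing:
        raise ValueError(f"class map contains ids without specs: {sorted(missing)}")

    N = config.n_composites
    t = np.arange(N)
    profiles = {}
    for s in config.class_specs:
        profiles[s.class_id] = (
            s.base_level
            + s.amp1 * np.cos(2 * np.pi * t / N - s.phase1)
            + s.amp2 * np.cos(4 * np.pi * t / N - s.phase2)
        )
    signal = np.zeros((N, config.n_rows, config.n_cols))
    for cid, prof in profiles.items():
        m = class_map.values == cid
        signal[:, m] = prof[:, None]

    rng = np.random.default_rng(np.random.SeedSequence([config.patch_seed, 1]))
    year_effect = rng.normal(0.0, config.year_effect_sd, size=config.n_years)
    stack = signal[None] + year_effect[:, None, None, None]
    if config.noise_sd > 0:
        stack = stack + rng.normal(0.0, config.noise_sd, size=stack.shape)
    return np.clip(stack, -1.0, 1.0)


def generate_covariate_map(class_map: ClassMap, config: SceneConfig,
                           categories: list[str] | None = None) -> tuple[Raster, list[str]]:
    """Categorical covariate raster derived from the class map.

    Each class maps to its spec's covariate_label; a covariate_noise fraction
    of pixels is flipped to a uniformly random other category so association
    tests face imperfect but directionally known structure.  Returns the
    integer raster (codes are 1-based indices into the category list) and the
    category list.
    """
    if categories is None:
        categories = list(dict.fromkeys(s.covariate_label for s in config.class_specs))
    code = {lab: i + 1 for i, lab in enumerate(categories)}
    out = np.zeros_like(class_map.values, dtype=np.int32)
    for s in config.class_specs:
        out[class_map.values == s.class_id] = code[s.covariate_label]
    if config.covariate_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.patch_seed, 2]))
        flip = rng.random(out.shape) < config.covariate_noise
        out[flip] = rng.integers(1, len(categories) + 1, size=int(flip.sum()))
    return (
        Raster(values=out, transform=config.transform, crs=config.crs, nodata=0),
        categories,
    )


def true_selection_ratios(class_map: ClassMap, config: SceneConfig) -> dict[int, float]:
    """Exact selection ratios implied by areas and fire multipliers.

    σ_c = m_c / Σ_k (a_k / A) m_k, so the area-weighted mean of σ is 1.
    """
    vals = class_map.values[class_map.mask()]
    total = vals.size
    areas = {s.class_id: int((vals == s.class_id).sum()) for s in config.class_specs}
    denom = sum((areas[s.class_id] / total) * s.fire_multiplier for s in config.class_specs)
    if denom == 0:
        raise ValueError("all fire multipliers are zero")
    return {s.class_id: s.fire_multiplier / denom for s in config.class_specs}


def generate_ignitions(class_map: ClassMap, config: SceneConfig) -> IgnitionSet:
    """Ignition points with per-class intensity ∝ area × fire_multiplier.

    Every point is uniform within its pixel; deterministic given fire_seed.
    """
    if config.n_fires <= 0:
        raise ValueError("n_fires must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.fire_seed, 0]))

    flat = class_map.values.ravel()
    valid = class_map.mask().ravel()
    weights = np.zeros(flat.size)
    for s in config.class_specs:
        weights[(flat == s.class_id) & valid] = s.fire_multiplier
    wsum = weights.sum()
    if wsum == 0:
        raise ValueError("all fire multipliers are zero: no ignition intensity anywhere")

    pix = rng.choice(flat.size, size=config.n_fires, p=weights / wsum)
    row, col = np.divmod(pix, config.n_cols)
    u = rng.random(config.n_fires)
    v = rng.random(config.n_fires)
    tr = config.transform
    x = tr.x0 + (col + u) * tr.dx
    y = tr.y0 + (row + v) * tr.dy
    return IgnitionSet(x=x, y=y)
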