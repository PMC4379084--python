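"""End-to-end orchestration: scene → Fourier → units → classes → statistics.

``run_all`` executes the full analysis from a single config and writes every
intermediate artifact (GeoTIFF rasters, CSV tables) plus a machine-readable
JSON report.  All randomized procedures receive explicit seeds recorded in
the report, so a completed run is reproducible from config + seeds alone;
the report deliberately contains no timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import association_tests as assoc
from . import fire_selectivity as fsel
from . import phenology_fourier as pf
from . import synthetic_scene as scene
from .raster import Raster, read_geotiff, write_geotiff
from .segmentation import SegParams, segment
from .unit_clustering import (cut_to_classes, split_largest_spatial,
                              unit_features, upgma_linkage)

__all__ = ["PipelineConfig", "run_all", "load_stack_dir", "write_stack_dir"]


@dataclass
class PipelineConfig:
    """Everything needed for one full run."""

    output_dir: str
    scene_config: scene.SceneConfig | None = None   # synthetic input
    stack_dir: str | None = None                    # or pre-existing rasters
    fires_csv: str | None = None
    covariate_raster: str | None = None
    covariate_categories: list[str] = field(default_factory=list)
    seg: SegParams = field(default_factory=SegParams)
    n_classes: int = 3
    split_largest: bool = True
    standardize_features: bool = False
    min_years_valid: int | None = None
    n_reps: int = 9999
    seed: int = 0
    tail: str = "double"

    def validate(self):
        if self.scene_config is None and (self.stack_dir is None or self.fires_csv is None):
            raise ValueError("config needs either a scene_config or stack_dir + fires_csv")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


def write_stack_dir(stack: np.ndarray, config: scene.SceneConfig, out_dir) -> None:
    """One single-band GeoTIFF per (year, composite): ndvi_<year>_<composite>.tif."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for y in range(stack.shape[0]):
        for t in range(stack.shape[1]):
            r = Raster(values=stack[y, t].astype(np.float32),
                       transform=config.transform, crs=config.crs, nodata=np.nan)
            write_geotiff(out / f"ndvi_{y}_{t}.tif", r)


def load_stack_dir(stack_dir) -> pf.NDVIStack:
    """Read a directory of ndvi_<year>_<composite>.tif files into a stack."""
    paths = sorted(Path(stack_dir).glob("ndvi_*.tif"))
    if not paths:
        raise ValueError(f"no ndvi_*.tif files in {stack_dir}")
    index = {}
    for p in paths:
        _, y, t = p.stem.split("_")
        index[(int(y), int(t))] = p
    years = sorted({y for y, _ in index})
    comps = sorted({t for _, t in index})
    first = read_geotiff(index[(years[0], comps[0])])
    shape = first.values.shape
    vals = np.full((len(years), len(comps)) + shape, np.nan)
    for i, y in enumerate(years):
        for j, t in enumerate(comps):
            r = read_geotiff(index[(y, t)])
            if r.crs != first.crs:
                raise ValueError(f"{index[(y, t)]}: CRS differs from the rest of the stack")
            vals[i, j] = r.values
    return pf.NDVIStack(values=vals, transform=first.transform, crs=first.crs,
                        years=years)


def _stage(name):
    """Wrap a stage so failures name the stage that broke."""
    def deco(fn):
        def inner(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return deco


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and return the JSON-serializable report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "n_reps": config.n_reps,
                    "parameters": {
                        "scale": config.seg.scale,
                        "shape_weight": config.seg.shape_weight,
                        "compactness_weight": config.seg.compactness_weight,
                        "min_pixels": config.seg.min_pixels,
                        "n_classes": config.n_classes,
                        "split_largest": config.split_largest,
                        "standardize_features": config.standardize_features,
                        "tail": config.tail,
                    }}

    # --- inputs -----------------------------------------------------------
    if config.scene_config is not None:
        sc = config.scene_config
        class_map = _stage("simulate")(scene.generate_class_map)(sc)
        stack_vals = _stage("simulate")(scene.generate_ndvi_stack)(class_map, sc)
        fires = _stage("simulate")(scene.generate_ignitions)(class_map, sc)
        cov_raster, cov_cats = _stage("simulate")(scene.generate_covariate_map)(class_map, sc)
        stack = pf.NDVIStack(values=stack_vals, transform=sc.transform, crs=sc.crs,
                             years=list(range(sc.n_years)))
        write_geotiff(out / "class_map.tif", class_map)
        write_geotiff(out / "covariate.tif", cov_raster)
        fires.to_csv(out / "fires.csv")
        sc.to_yaml(out / "scene.yaml")
        report["inputs"] = {"kind": "synthetic", "n_fires": len(fires),
                            "true_sigma": scene.true_selection_ratios(class_map, sc)}
    else:
        stack = _stage("load")(load_stack_dir)(config.stack_dir)
        fires = _stage("load")(scene.IgnitionSet.from_csv)(config.fires_csv)
        cov_raster = (read_geotiff(config.covariate_raster)
                      if config.covariate_raster else None)
        cov_cats = config.covariate_categories or None
        report["inputs"] = {"kind": "files", "stack_dir": str(config.stack_dir),
                            "n_fires": len(fires)}

    # --- fourier ----------------------------------------------------------
    profiles = _stage("fourier")(pf.mean_seasonal_profile)(stack, config.min_years_valid)
    fourier = _stage("fourier")(pf.tfa_image)(profiles)
    write_geotiff(out / "fourier.tif", fourier.to_raster())

    # --- segmentation -----------------------------------------------------
    units = _stage("segment")(segment)(fourier, config.seg)
    write_geotiff(out / "units.tif", units.to_raster())
    units.table.to_csv(out / "units.csv", index=False)
    report["segmentation"] = {"n_units": int(len(units.table))}

    # --- clustering -------------------------------------------------------
    feats = _stage("cluster")(unit_features)(units, fourier)
    k = min(config.n_classes, len(feats))
    if len(feats) >= 2:
        tree = _stage("cluster")(upgma_linkage)(feats, config.standardize_features)
        assignment = _stage("cluster")(cut_to_classes)(tree, k, feats)
        np.savetxt(out / "linkage.csv", tree.linkage, delimiter=",",
                   header="node_a,node_b,height,size", comments="")
        (out / "dendrogram.nwk").write_text(tree.to_newick())
        largest_n = assignment.assignment["pfc_label"].value_counts().max()
        if config.split_largest and largest_n >= 2:
            assignment = _stage("cluster")(split_largest_spatial)(
                assignment, feats, seed=config.seed)
    else:
        import pandas as pd
        assignment_df = pd.DataFrame({"unit_id": feats.table["unit_id"], "pfc_label": "PFC1"})
        from .unit_clustering import ClassAssignment
        assignment = ClassAssignment(assignment=assignment_df)
    assignment.assignment.to_csv(out / "assignment.csv", index=False)

    pfc_names = sorted(assignment.assignment["pfc_label"].unique())
    pfc_code = {lab: i + 1 for i, lab in enumerate(pfc_names)}
    pfc_raster_vals = np.zeros_like(units.labels, dtype=np.int32)
    unit_to_class = dict(zip(assignment.assignment["unit_id"],
                             assignment.assignment["pfc_label"]))
    for uid, lab in unit_to_class.items():
        pfc_raster_vals[units.labels == uid] = pfc_code[lab]
    pfc_raster = Raster(values=pfc_raster_vals, transform=units.transform,
                        crs=units.crs, nodata=0)
    write_geotiff(out / "pfc.tif", pfc_raster)
    report["clustering"] = {"k": int(k), "classes": pfc_names}

    # --- selectivity ------------------------------------------------------
    pu_counts, n_excluded = _stage("selectivity")(fsel.count_fires_per_zone)(units, fires)
    pu_areas = units.table.set_index("unit_id").loc[pu_counts.index, "area_km2"]
    pu_sigma = fsel.selection_ratios(pu_counts.to_numpy(), pu_areas.to_numpy())
    pu_labels = np.array([unit_to_class[u] for u in pu_counts.index])

    class_counts = {lab: int(pu_counts.to_numpy()[pu_labels == lab].sum())
                    for lab in pfc_names}
    class_areas = {lab: float(pu_areas.to_numpy()[pu_labels == lab].sum())
                   for lab in pfc_names}
    mc = _stage("selectivity")(fsel.monte_carlo_sigma_test)(
        np.array([class_counts[c] for c in pfc_names]),
        np.array([class_areas[c] for c in pfc_names]),
        n_reps=config.n_reps, seed=config.seed, tail=config.tail)
    mc_tab = mc.table.assign(zone=pfc_names)
    mc_tab.to_csv(out / "class_selectivity.csv", index=False)

    anova_res = None
    pairwise = None
    if len(pfc_names) >= 2 and len(pu_sigma) - len(pfc_names) >= 1:
        anova_res = _stage("selectivity")(fsel.permutation_anova)(
            pu_sigma, pu_labels, n_perms=config.n_reps, seed=config.seed)
        pairwise = _stage("selectivity")(fsel.pairwise_permutation_f)(
            pu_sigma, pu_labels, n_perms=config.n_reps, seed=config.seed)
        pairwise.to_csv(out / "pairwise_f.csv", index=False)

    report["selectivity"] = {
        "n_fires_excluded": int(n_excluded),
        "per_class": {c: {"n_fires": class_counts[c], "area_km2": class_areas[c],
                          "sigma": float(mc_tab.set_index("zone").loc[c, "sigma"]),
                          "p_value": float(mc_tab.set_index("zone").loc[c, "p_value"])}
                      for c in pfc_names},
        "anova": None if anova_res is None else {
            "F": anova_res.F_observed, "p_value": anova_res.p_value,
            "n_permutations": anova_res.n_permutations},
    }

    # --- association ------------------------------------------------------
    if cov_raster is not None:
        pfc_per_fire, _ = _fire_labels(pfc_raster, fires)
        cov_per_fire, _ = _fire_labels(cov_raster, fires)
        keep = (pfc_per_fire > 0) & (cov_per_fire > 0)
        code_to_pfc = {v: k for k, v in pfc_code.items()}
        pfc_lab = [code_to_pfc[c] for c in pfc_per_fire[keep]]
        if cov_cats:
            cov_lab = [cov_cats[c - 1] for c in cov_per_fire[keep]]
        else:
            cov_lab = [str(c) for c in cov_per_fire[keep]]
        res = _stage("associate")(assoc.margin_fixed_randomization)(
            pfc_lab, cov_lab, n_reps=config.n_reps, seed=config.seed,
            tail=config.tail)
        res.observed.to_csv(out / "contingency.csv")
        res.cell_p.to_csv(out / "contingency_cell_p.csv")
        report["association"] = {"chi2": res.chi2_observed, "p_value": res.p_value,
                                 "n_fires_used": int(keep.sum())}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _fire_labels(raster: Raster, fires) -> tuple[np.ndarray, int]:
    row, col = raster.transform.rowcol(fires.x, fires.y)
    rows, cols = raster.values.shape[-2:]
    inside = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
    lab = np.zeros(len(fires.x), dtype=np.int64)
    lab[inside] = raster.values[row[inside], col[inside]]
    return lab, int((~inside).sum())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
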