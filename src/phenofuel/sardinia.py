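"""Published summary tables for the Sardinian fuel-phenology case study.

Sardinia (~24,000 km²) was mapped into four phenological fuel classes from
2000–2012 MODIS NDVI seasonal composites; 28,744 ignition points recorded
April–October 2000–2010 were overlaid on the classes, on seven aggregated
CORINE land-cover macro-classes and on three climatic regions.  These
tabulations are the published class-level summaries; they serve as reference
inputs for desk-scale recomputation of the selection ratios and χ²
statistics (the underlying imagery and per-fire records are not
redistributable).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PFC_LABELS", "FIRE_COUNTS", "AREAS_KM2", "CLC_BY_PFC",
           "CLIMATE_BY_PFC", "labels_from_table"]

PFC_LABELS = ["PFC1", "PFC2a", "PFC2b", "PFC3"]

#: Ignition counts per phenological fuel class, 2000-2010.
FIRE_COUNTS = pd.Series([10690, 10341, 4928, 2785], index=PFC_LABELS, name="n_fires")

#: Class areas in km².
AREAS_KM2 = pd.Series([4210.25, 5759.63, 5743.31, 6691.31], index=PFC_LABELS,
                      name="area_km2")

#: Ignitions cross-classified by land-cover macro-class and fuel class.
CLC_BY_PFC = pd.DataFrame(
    [
        [852, 880, 353, 110],
        [5921, 3350, 754, 129],
        [521, 760, 216, 27],
        [2598, 3324, 1699, 673],
        [176, 242, 334, 872],
        [241, 808, 386, 71],
        [381, 977, 1186, 903],
    ],
    index=[
        "urban_areas",
        "arable_lands",
        "permanent_crops",
        "heterogeneous_agricultural",
        "forests",
        "grasslands_pastures",
        "shrublands",
    ],
    columns=PFC_LABELS,
)

#: Ignitions cross-classified by climatic region and fuel class.
CLIMATE_BY_PFC = pd.DataFrame(
    [
        [8313, 6093, 1290, 561],
        [0, 317, 633, 939],
        [2377, 3931, 3005, 1285],
    ],
    index=["mediterranean", "transitional_mediterranean", "transitional_temperate"],
    columns=PFC_LABELS,
)


def labels_from_table(table: pd.DataFrame) -> tuple[list, list]:
    """Expand a contingency table into the equivalent per-fire label vectors.

    Returns (column_labels, row_labels) with one entry per fire, in a fixed
    deterministic order; re-tabulating them reproduces the table exactly.
    """
    col_labels: list = []
    row_labels: list = []
    for r in table.index:
        for c in table.columns:
            k = int(table.loc[r, c])
            col_labels.extend([c] * k)
            row_labels.extend([r] * k)
    return col_labels, row_labels
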