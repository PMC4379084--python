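"""Minimal georeferenced raster container and GeoTIFF round-trip.

A raster here is an array plus an affine geotransform, a CRS string and an
optional nodata value.  Only north-up transforms (no rotation/shear) are
supported, which is all the pipeline ever produces or consumes.  Files are
written as GeoTIFFs through :mod:`tifffile`, with the geotransform encoded in
the standard ``ModelPixelScale``/``ModelTiepoint`` tags and the CRS and nodata
value carried in a JSON ``ImageDescription``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["GridTransform", "Raster", "read_geotiff", "write_geotiff"]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform: map = origin + pixel_index * step.

    ``x0, y0`` is the outer corner of the top-left pixel; ``dx > 0`` and
    ``dy < 0`` for the usual row-down orientation.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def xy(self, row: np.ndarray, col: np.ndarray, offset: float = 0.5):
        """Map coordinates of pixel (row, col); offset 0.5 = pixel center."""
        x = self.x0 + (np.asarray(col) + offset) * self.dx
        y = self.y0 + (np.asarray(row) + offset) * self.dy
        return x, y

    def rowcol(self, x: np.ndarray, y: np.ndarray):
        """Pixel indices containing map points, half-open interval convention.

        A point exactly on a shared pixel edge belongs to the pixel whose
        half-open interval [edge, edge + step) contains it.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.dx).astype(np.int64)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.dy).astype(np.int64)
        return row, col


@dataclass
class Raster:
    """Array + georeferencing. ``values`` is (rows, cols) or (bands, rows, cols)."""

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:32632"
    nodata: float | int | None = None

    @property
    def shape(self):
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean mask of valid pixels (2-D; all-band validity for stacks)."""
        if self.nodata is None:
            return np.ones(self.values.shape[-2:], dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating) and np.isnan(self.nodata):
            bad = np.isnan(self.values)
        else:
            bad = self.values == self.nodata
        if self.values.ndim == 3:
            bad = bad.any(axis=0)
        return ~bad


def write_geotiff(path, raster: Raster) -> None:
    arr = np.asarray(raster.values)
    if arr.ndim not in (2, 3):
        raise ValueError("raster array must be 2-D or 3-D (bands, rows, cols)")
    t = raster.transform
    desc = json.dumps(
        {"crs": raster.crs, "nodata": raster.nodata, "transform": [t.x0, t.y0, t.dx, t.dy]}
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (abs(t.dx), abs(t.dy), 0.0), True),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0), True),
    ]
    kwargs = {}
    if arr.ndim == 3:
        kwargs = {"photometric": "minisblack", "planarconfig": "separate"}
    tifffile.imwrite(str(path), arr, description=desc, extratags=extratags,
                     metadata=None, **kwargs)


def read_geotiff(path) -> Raster:
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        desc = page.tags.get("ImageDescription")
        try:
            meta = json.loads(desc.value) if desc is not None else {}
        except (TypeError, json.JSONDecodeError):
            meta = {}
        scale = page.tags.get(_MODEL_PIXEL_SCALE)
        tie = page.tags.get(_MODEL_TIEPOINT)
    if "transform" in meta:
        x0, y0, dx, dy = meta["transform"]
        transform = GridTransform(x0, y0, dx, dy)
    elif scale is not None and tie is not None:
        sx, sy, _ = scale.value[:3]
        transform = GridTransform(tie.value[3], tie.value[4], sx, -sy)
    else:
        raise ValueError(f"{path}: no georeferencing found")
    return Raster(
        values=arr,
        transform=transform,
        crs=meta.get("crs", ""),
        nodata=meta.get("nodata"),
    )
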