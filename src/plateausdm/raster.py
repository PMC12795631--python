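"""Georeferenced grid rasters and aligned stacks.

A :class:`GridRaster` is one single-band layer on a regular square-cell grid
with an explicit nodata mask; a :class:`RasterStack` is a named, grid-aligned
collection of layers describing one scenario's environment. Rasters are read
and written as single-band GeoTIFF through :mod:`tifffile`, carrying the
georeferencing (pixel scale + top-left tiepoint), the CRS label and the
nodata value as standard GeoTIFF/GDAL tags.

No resampling or reprojection is performed anywhere: stacks are validated to
share grid geometry exactly, mirroring a workflow in which all layers were
standardized to a common coordinate system, resolution and extent upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import tifffile

from ._util import log_stage

#: Environmental variable vocabulary used throughout the pipeline.
VARIABLE_VOCAB = ("Bio2", "Bio3", "Bio12", "Bio15", "Bio17", "ELE", "LUCC", "HII")

#: Variables treated as categorical (integer class codes, one-hot features).
CATEGORICAL_VARS = ("LUCC",)

#: Variables held constant when projecting to future scenarios.
STATIC_VARS = ("ELE", "HII")

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113

_FLOAT_NODATA = -3.4e38
_INT_NODATA = -9999


class RasterError(ValueError):
    """Raised for malformed raster files or mismatched grid geometry."""


@dataclass
class GridRaster:
    """One single-band raster layer.

    Parameters
    ----------
    values
        2-D array of cell values (float for continuous layers, integer codes
        for categorical layers). Values under the mask are undefined.
    nodata_mask
        2-D boolean array, same shape; ``True`` marks nodata cells.
    origin_x, origin_y
        Map coordinates of the grid's top-left corner.
    cell_size
        Side length of the (square) cells in map units; must be positive.
    crs_label
        Free-text identifier of the coordinate reference system.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise RasterError("values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise RasterError("values and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise RasterError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def geometry(self) -> Tuple:
        return (self.shape, float(self.origin_x), float(self.origin_y),
                float(self.cell_size), self.crs_label)

    def same_geometry(self, other: "GridRaster", tol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and abs(self.origin_x - other.origin_x) <= tol
                and abs(self.origin_y - other.origin_y) <= tol
                and abs(self.cell_size - other.cell_size) <= tol
                and self.crs_label == other.crs_label)

    def cell_center(self, row, col):
        """Map coordinates of the center of cell (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x, y):
        """Cell indices containing point(s) under half-open cell intervals.

        A cell spans ``[left, right)`` in x and ``(bottom, top]`` in y, so
        every point maps to exactly one cell.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def contains(self, x, y):
        """Whether point(s) fall inside the raster bounding box."""
        row, col = self.point_to_cell(x, y)
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    def copy_with(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "GridRaster":
        return replace(self, values=values,
                       nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask)


@dataclass
class RasterStack:
    """Named, grid-aligned set of layers for one scenario.

    Use :func:`align_stack` to construct one with geometry validation.
    """

    layers: Dict[str, GridRaster]
    scenario_tag: str = "current"

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.layers)

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def grid(self) -> GridRaster:
        """Representative layer carrying the shared grid geometry."""
        return next(iter(self.layers.values()))

    @property
    def valid_mask(self) -> np.ndarray:
        """Combined valid mask: cell-wise AND over all layers."""
        mask = np.ones(self.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.valid_mask
        return mask

    def continuous_names(self) -> Tuple[str, ...]:
        return tuple(n for n in self.layers if n not in CATEGORICAL_VARS)

    def categorical_names(self) -> Tuple[str, ...]:
        return tuple(n for n in self.layers if n in CATEGORICAL_VARS)

    def subset(self, names: Iterable[str]) -> "RasterStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise RasterError(f"stack {self.scenario_tag!r} lacks layers {missing}")
        return RasterStack({n: self.layers[n] for n in names}, self.scenario_tag)


def align_stack(layers: Mapping[str, GridRaster], scenario_tag: str = "current",
                enforce_vocab: bool = True) -> RasterStack:
    """Validate that all layers share grid geometry and build a stack.

    This validates only — it never resamples. Any geometry mismatch raises
    :class:`RasterError` naming the offending layer and field, and an empty
    combined valid mask is rejected.
    """
    if not layers:
        raise RasterError("align_stack requires at least one layer")
    if enforce_vocab:
        unknown = [n for n in layers if n not in VARIABLE_VOCAB]
        if unknown:
            raise RasterError(f"unknown layer names {unknown}; expected subset of {VARIABLE_VOCAB}")
    items = list(layers.items())
    ref_name, ref = items[0]
    for name, layer in items[1:]:
        for fld in ("shape", "origin_x", "origin_y", "cell_size", "crs_label"):
            a, b = getattr(ref, fld), getattr(layer, fld)
            same = a == b if fld in ("shape", "crs_label") else abs(a - b) <= 1e-9
            if not same:
                raise RasterError(
                    f"layer {name!r} does not match {ref_name!r} on {fld}: {b!r} != {a!r}")
    stack = RasterStack(dict(items), scenario_tag=scenario_tag)
    if not stack.valid_mask.any():
        raise RasterError("combined valid mask is empty")
    return stack


# -- GeoTIFF I/O ----------------------------------------------------------


def write_raster(raster: GridRaster, path: str | os.PathLike) -> None:
    """Write a single-band GeoTIFF.

    Integer rasters round-trip bit-identically; float rasters are stored as
    float64 and round-trip exactly as well. Nodata cells are written as a
    sentinel declared in the GDAL_NODATA tag.
    """
    values = raster.values
    if np.issubdtype(values.dtype, np.integer) or values.dtype == bool:
        data = values.astype(np.int32).copy()
        nodata = _INT_NODATA
    else:
        data = values.astype(np.float64).copy()
        nodata = _FLOAT_NODATA
    data[raster.nodata_mask] = nodata
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(raster.cell_size), float(raster.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(raster.origin_x), float(raster.origin_y), 0.0)),
        (_TAG_GEO_ASCII, "s", None, raster.crs_label + "|"),
        (_TAG_GDAL_NODATA, "s", None, repr(nodata)),
    ]
    tifffile.imwrite(os.fspath(path), data, extratags=extratags)


def read_raster(path: str | os.PathLike) -> GridRaster:
    """Read a single-band georeferenced GeoTIFF written by :func:`write_raster`
    (or any minimal GeoTIFF carrying pixel-scale and tiepoint tags)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise RasterError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise RasterError(f"{path}: expected a single band, found {len(tf.pages)} pages")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise RasterError(f"{path}: expected a single band, found {page.samplesperpixel} samples")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterError(f"{path}: missing georeferencing (pixel-scale/tiepoint tags)")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-9:
            raise RasterError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
        tie = tags[_TAG_TIEPOINT].value
        origin_x, origin_y = float(tie[3]), float(tie[4])
        crs_label = "unknown"
        if _TAG_GEO_ASCII in tags:
            crs_label = str(tags[_TAG_GEO_ASCII].value).rstrip("|")
        values = page.asarray()
        if values.ndim != 2:
            raise RasterError(f"{path}: expected 2-D data, got shape {values.shape}")
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        else:
            nodata = _INT_NODATA if np.issubdtype(values.dtype, np.integer) else _FLOAT_NODATA
        if np.issubdtype(values.dtype, np.integer):
            mask = values == int(nodata)
        else:
            mask = np.isclose(values, nodata, rtol=1e-6) | np.isnan(values)
    raster = GridRaster(values=values, nodata_mask=mask, origin_x=origin_x,
                        origin_y=origin_y, cell_size=float(sx), crs_label=crs_label)
    if not raster.valid_mask.any():
        log_stage("read_raster", path=path, warning="all cells are nodata")
    return raster
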