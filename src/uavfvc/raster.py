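"""Georeferenced raster containers and plain-file I/O.

Rasters are stored north-up with pixel-center world coordinates: the pixel at
(row, col) is centered at ``x = origin_x + (col + 0.5) * pixel_size`` and
``y = origin_y - (row + 0.5) * pixel_size``, where (origin_x, origin_y) is the
top-left corner of the grid. Files are written as plain TIFF with the
geotransform embedded as a JSON ImageDescription tag, so every artifact stays
readable without GIS tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine grid placement (top-left corner origin, square pixels)."""

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def rowcol_to_xy(self, row, col):
        """World coordinates of pixel centers."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def xy_to_rowcol(self, x, y):
        """Integer pixel indices containing world points (floor convention)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.pixel_size)
        row = np.floor((self.origin_y - np.asarray(y)) / self.pixel_size)
        return row.astype(np.int64), col.astype(np.int64)

    def bounds(self, shape):
        """(xmin, ymin, xmax, ymax) of the raster footprint for a (rows, cols) shape."""
        rows, cols = shape
        return (
            self.origin_x,
            self.origin_y - rows * self.pixel_size,
            self.origin_x + cols * self.pixel_size,
            self.origin_y,
        )


@dataclass
class RGBRaster:
    """8-bit 3-band visible image on a georeferenced grid.

    ``bands`` has shape (rows, cols, 3) in R, G, B order; an optional boolean
    ``nodata_mask`` marks pixels to exclude from every computation.
    """

    bands: np.ndarray
    transform: GeoTransform = GeoTransform()
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3 or self.bands.shape[2] != 3:
            raise ValueError("bands must have shape (rows, cols, 3)")
        if self.bands.min() < 0 or self.bands.max() > 255:
            raise ValueError("band values must lie in [0, 255]")
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.bands.shape[:2]:
                raise ValueError("nodata_mask shape must match the grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    @property
    def r(self) -> np.ndarray:
        return self.bands[..., 0].astype(np.float64)

    @property
    def g(self) -> np.ndarray:
        return self.bands[..., 1].astype(np.float64)

    @property
    def b(self) -> np.ndarray:
        return self.bands[..., 2].astype(np.float64)


def write_raster(path, array, transform: GeoTransform, *, meta: dict | None = None) -> None:
    """Write a single- or multi-band raster as TIFF with a JSON geotransform tag."""
    desc = {
        "origin_x": transform.origin_x,
        "origin_y": transform.origin_y,
        "pixel_size": transform.pixel_size,
    }
    if meta:
        desc.update(meta)
    tifffile.imwrite(str(path), np.asarray(array), description=json.dumps(desc))


def read_raster(path) -> tuple[np.ndarray, GeoTransform]:
    """Read a raster written by :func:`write_raster`; returns (array, transform)."""
    with tifffile.TiffFile(str(path)) as tif:
        array = tif.asarray()
        desc = tif.pages[0].description
    transform = GeoTransform()
    if desc:
        try:
            d = json.loads(desc)
            transform = GeoTransform(
                float(d.get("origin_x", 0.0)),
                float(d.get("origin_y", 0.0)),
                float(d.get("pixel_size", 1.0)),
            )
        except (ValueError, TypeError):
            pass
    return array, transform


def read_rgb(path) -> RGBRaster:
    array, transform = read_raster(path)
    return RGBRaster(array, transform)


__all__ = [
    "GeoTransform",
    "RGBRaster",
    "write_raster",
    "read_raster",
    "read_rgb",
]
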