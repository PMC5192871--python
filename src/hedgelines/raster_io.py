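"""Read and write rasters as ESRI ASCII grid or GeoTIFF.

The ASCII grid format is the plain-text interchange format
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header followed
by rows north to south).  GeoTIFF support writes the georeferencing the
standard way — ModelPixelScale (33550), ModelTiepoint (33922, tying pixel
(0,0) to the top-left corner) and GDAL's ASCII nodata tag (42113) — via
tifffile, so outputs open in GDAL/QGIS.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import tifffile

from .errors import ParameterError
from .grids import DEFAULT_NODATA, HeightGrid, LandCoverGrid

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_ascii_grid(grid: HeightGrid | LandCoverGrid, path: str | os.PathLike,
                     fmt: str = "%.6g") -> None:
    """Write a grid as an ESRI ASCII grid (.asc)."""
    nodata = getattr(grid, "nodata", DEFAULT_NODATA)
    yll = grid.origin_y - grid.values.shape[0] * grid.cell_size
    header = (
        f"ncols {grid.values.shape[1]}\n"
        f"nrows {grid.values.shape[0]}\n"
        f"xllcorner {grid.origin_x:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {nodata:.6g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt=fmt)


def read_ascii_grid(path: str | os.PathLike, nodata_default: float = DEFAULT_NODATA
                    ) -> HeightGrid:
    """Read an ESRI ASCII grid into a :class:`HeightGrid`."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in meta:
            raise ParameterError(f"ASCII grid header missing {key}: {path}")
    nrows, ncols = int(meta["nrows"]), int(meta["ncols"])
    if values.shape != (nrows, ncols):
        raise ParameterError(
            f"ASCII grid body shape {values.shape} does not match header "
            f"({nrows}, {ncols}): {path}"
        )
    origin_y = meta["yllcorner"] + nrows * meta["cellsize"]
    return HeightGrid(
        origin_x=meta["xllcorner"],
        origin_y=origin_y,
        cell_size=meta["cellsize"],
        values=values,
        nodata=meta.get("nodata_value", nodata_default),
    )


def write_geotiff(grid: HeightGrid | LandCoverGrid, path: str | os.PathLike) -> None:
    """Write a single-band GeoTIFF with planar georeferencing tags."""
    nodata = getattr(grid, "nodata", None)
    values = grid.values
    dtype = np.int32 if np.issubdtype(values.dtype, np.integer) else np.float32
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, f"{nodata:.6g}"))
    tifffile.imwrite(path, values.astype(dtype), extratags=extratags)


def read_geotiff(path: str | os.PathLike, nodata_default: float = DEFAULT_NODATA
                 ) -> HeightGrid:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF carrying pixel-scale and tiepoint tags)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ParameterError(f"TIFF lacks georeferencing tags: {path}")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        if abs(sx - sy) > 1e-9:
            raise ParameterError(f"non-square pixels not supported: {path}")
        nodata = nodata_default
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    # tiepoint maps raster (i, j) -> model (x, y); we require the (0,0) corner
    origin_x = tie[3] - tie[0] * sx
    origin_y = tie[4] + tie[1] * sy
    return HeightGrid(origin_x, origin_y, float(sx), np.asarray(values, dtype=float),
                      nodata)


def as_landcover(grid: HeightGrid, legend: Mapping[int, str]) -> LandCoverGrid:
    """Reinterpret a numeric grid read from disk as a categorical one."""
    return LandCoverGrid(grid.origin_x, grid.origin_y, grid.cell_size,
                         grid.values.astype(int), legend)


def write_legend(legend: Mapping[int, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for code in sorted(legend):
            fh.write(f"{code},{legend[code]}\n")


def read_legend(path: str | os.PathLike) -> dict[int, str]:
    legend: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            code, name = line.split(",", 1)
            legend[int(code)] = name.strip()
    return legend
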