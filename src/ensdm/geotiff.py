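"""Single-band GeoTIFF I/O for geographic (lon/lat) rasters.

Rasters are written as float32 with the standard GeoTIFF tags: pixel scale,
tie point anchoring the north-west corner, a minimal GeoKey directory marking
a geographic WGS84 CRS, and the GDAL nodata tag.  Files without
georeferencing tags are rejected rather than silently assigned a grid.
"""

from __future__ import annotations

import math
import os

import numpy as np
import tifffile

from .grids import GridSpec, Raster

NODATA = -9999.0

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKeys: geographic model, pixel-is-area, EPSG:4326
_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def write_geotiff(raster: Raster, path: str | os.PathLike) -> None:
    """Write a raster as a single-band float32 GeoTIFF with nodata = -9999."""
    g = raster.grid
    data = raster.values.astype(np.float32)
    data[raster.mask] = np.float32(NODATA)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.resolution, g.resolution, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.lon_min, g.lat_max, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS), _GEOKEYS),
        (_GDAL_NODATA, "s", 0, str(NODATA)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_geotiff(path: str | os.PathLike) -> Raster:
    """Read a single-band geographic GeoTIFF back into a :class:`Raster`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        if _GEO_KEY_DIRECTORY not in tags:
            raise ValueError(f"{path}: missing GeoKey directory (no CRS)")
        nodata = NODATA
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)

    res_x, res_y = float(scale[0]), float(scale[1])
    if not math.isclose(res_x, res_y, rel_tol=1e-9):
        raise ValueError(f"{path}: anisotropic pixels not supported")
    # tie point maps raster (0,0) corner to (lon, lat) of the NW corner
    lon_min = float(tie[3]) - float(tie[0]) * res_x
    lat_max = float(tie[4]) + float(tie[1]) * res_y
    n_rows, n_cols = data.shape
    grid = GridSpec(
        lon_min=lon_min,
        lon_max=lon_min + n_cols * res_x,
        lat_min=lat_max - n_rows * res_y,
        lat_max=lat_max,
        resolution=res_x,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    values = data.astype(float)
    mask = ~np.isfinite(values) | np.isclose(values, nodata)
    values[mask] = np.nan
    return Raster(grid, values, mask)
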