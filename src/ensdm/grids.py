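"""Geographic grids, in-memory rasters and predictor stacks.

All spatial data in this package live on a regular longitude/latitude lattice
(cell-center registered, row 0 = northernmost row) on a spherical datum with
radius ``EARTH_RADIUS_KM``.  Point-to-cell assignment uses half-open intervals
``[edge, edge + resolution)`` measured from the north-west corner, so a point
on a shared edge belongs to exactly one cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_KM = 6371.0

#: canonical predictor order used throughout the package
PREDICTOR_NAMES = ("BIO1", "BIO4", "BIO12", "BIO15", "Urban", "Crop", "Pasture")
LANDUSE_NAMES = ("Urban", "Crop", "Pasture")


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat lattice.

    ``n_cols = round((lon_max - lon_min)/resolution)`` and likewise for rows;
    cell centers sit at ``edge + (i + 0.5) * resolution``.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float
    n_rows: int = field(default=0)
    n_cols: int = field(default=0)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("inverted or empty extent")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must lie within [-90, 90]")
        if self.n_rows == 0 or self.n_cols == 0:
            object.__setattr__(
                self, "n_rows", int(round((self.lat_max - self.lat_min) / self.resolution))
            )
            object.__setattr__(
                self, "n_cols", int(round((self.lon_max - self.lon_min) / self.resolution))
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (row order)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices for points; -1 marks points outside the grid.

        Half-open assignment: a point exactly on an interior edge belongs to the
        cell whose origin (NW corner) it touches.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((self.lat_max - lat) / self.resolution).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            math.isclose(self.lon_min, other.lon_min)
            and math.isclose(self.lon_max, other.lon_max)
            and math.isclose(self.lat_min, other.lat_min)
            and math.isclose(self.lat_max, other.lat_max)
            and math.isclose(self.resolution, other.resolution)
            and self.shape == other.shape
        )

    __hash__ = None  # type: ignore[assignment]


def make_grid(extent: tuple[float, float, float, float], resolution: float) -> GridSpec:
    """Build a :class:`GridSpec` from ``(lon_min, lon_max, lat_min, lat_max)``.

    If the extent is not an integer multiple of the resolution it is expanded
    outward (lon_max / lat_max grow) to the next whole cell.
    """
    lon_min, lon_max, lat_min, lat_max = map(float, extent)
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("inverted extent")
    n_cols = math.ceil((lon_max - lon_min) / resolution - 1e-9)
    n_rows = math.ceil((lat_max - lat_min) / resolution - 1e-9)
    return GridSpec(
        lon_min=lon_min,
        lon_max=lon_min + n_cols * resolution,
        lat_min=lat_min,
        lat_max=lat_min + n_rows * resolution,
        resolution=resolution,
        n_rows=n_rows,
        n_cols=n_cols,
    )


@dataclass
class Raster:
    """A single-band raster: values plus a nodata mask on a :class:`GridSpec`.

    ``mask`` is True where the cell holds NO data; masked cells are excluded
    from every statistic computed in this package.
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape mismatch")
            self.mask = self.mask | ~np.isfinite(self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = fill
        return out

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.mask.copy())


class PredictorStack:
    """An ordered set of co-registered predictor rasters with a joint mask.

    The stack's valid mask is the conjunction of the per-layer masks: a cell
    is usable only where every layer has data.  Fractional land-use layers
    (Urban/Crop/Pasture) are percentages in [0, 100].
    """

    def __init__(self, grid: GridSpec, layers: dict[str, Raster] | None = None):
        self.grid = grid
        self.layers: dict[str, Raster] = {}
        if layers:
            for name, rast in layers.items():
                self.add_layer(name, rast)

    def add_layer(self, name: str, raster: Raster) -> None:
        if raster.grid != self.grid:
            raise ValueError(f"layer {name!r} is not on the stack grid")
        self.layers[name] = raster

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        """True where ALL layers are non-missing (shrinks as layers are added)."""
        out = np.ones(self.grid.shape, dtype=bool)
        for rast in self.layers.values():
            out &= rast.valid
        return out

    def extract(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Predictor matrix (n_points, n_layers) at cell indices; NaN where masked."""
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        out = np.empty((rows.size, len(self.layers)), dtype=float)
        for k, rast in enumerate(self.layers.values()):
            vals = rast.values[rows, cols]
            bad = rast.mask[rows, cols]
            vals = np.where(bad, np.nan, vals)
            out[:, k] = vals
        return out

    def as_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, X) for every valid cell, row-major order."""
        rr, cc = np.nonzero(self.valid_mask)
        return rr, cc, self.extract(rr, cc)

    def copy(self) -> "PredictorStack":
        return PredictorStack(self.grid, {n: r.copy() for n, r in self.layers.items()})


def resample_to_grid(src: Raster, target: GridSpec, method: str = "bilinear") -> Raster:
    """Resample a raster onto another grid by sampling at target cell centers.

    ``bilinear`` interpolates between the four surrounding source cell centers
    and is reserved for continuous fields; ``nearest`` snaps to the closest
    source center (ties resolved toward the lower coordinate, scipy's
    convention) and is used for masks and categorical layers.  Target cells
    outside the source center lattice, or whose interpolation touches a nodata
    source cell, come back masked.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    if (
        src.grid.lon_max <= target.lon_min
        or target.lon_max <= src.grid.lon_min
        or src.grid.lat_max <= target.lat_min
        or target.lat_max <= src.grid.lat_min
    ):
        raise ValueError("source and target extents are disjoint")

    # RegularGridInterpolator needs ascending axes: flip latitude (row 0 = north).
    src_lat = src.grid.lat_centers()[::-1]
    src_lon = src.grid.lon_centers()
    vals = src.filled(np.nan)[::-1, :]
    interp = RegularGridInterpolator(
        (src_lat, src_lon),
        vals,
        method="linear" if method == "bilinear" else "nearest",
        bounds_error=False,
        fill_value=np.nan,
    )
    tlat = target.lat_centers()
    tlon = target.lon_centers()
    glat, glon = np.meshgrid(tlat, tlon, indexing="ij")
    out = interp(np.column_stack([glat.ravel(), glon.ravel()])).reshape(target.shape)
    return Raster(target, out)


def cell_area_raster(grid: GridSpec) -> Raster:
    """Geodesic cell areas in km² (spherical zone formula, constant per row).

    area(row) = R² · Δλ · (sin φ_top − sin φ_bottom) with R = 6371 km.
    """
    res = math.radians(grid.resolution)
    lat_top = np.deg2rad(grid.lat_max - np.arange(grid.n_rows) * grid.resolution)
    lat_bot = lat_top - math.radians(grid.resolution)
    band = EARTH_RADIUS_KM**2 * res * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(band[:, None], grid.n_cols, axis=1)
    return Raster(grid, values, np.zeros(grid.shape, dtype=bool))


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km on the package's spherical datum."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def clip_landuse(stack: PredictorStack) -> PredictorStack:
    """Clip fractional land-use layers to [0, 100] in place (bilinear overshoot)."""
    for name in LANDUSE_NAMES:
        if name in stack.layers:
            rast = stack.layers[name]
            np.clip(rast.values, 0.0, 100.0, out=rast.values)
    return stack


def warn_once(message: str) -> None:
    warnings.warn(message, stacklevel=3)
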