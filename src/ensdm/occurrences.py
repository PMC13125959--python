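"""Occurrence cleaning, thinning, grid aggregation, and background sampling.

The cleaning protocol mirrors standard presence-only practice: exact
duplicates (species + coordinates) are collapsed, records outside the study
extent or off the land mask are dropped, and a temporal window (default
2014-2024) keeps records contemporary with the predictors.  Spatial thinning
retains one record per 1 km x 1 km cell of a local metric grid.  Thinned
records are aggregated to the modeling grid, and pseudo-absences are drawn
uniformly without replacement from an accessible-area background — either
the full valid domain or a coastal buffer (cells whose centers lie within a
great-circle distance of the coastline) — at a fixed presence:absence ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, PredictorStack, Raster, haversine_km

OCCURRENCE_COLUMNS = ("species", "lon", "lat", "year")
KM_PER_DEG = 111.195  # spherical degree of latitude, R = 6371 km


@dataclass
class FilterReport:
    """Counts of records removed at each cleaning stage."""

    n_input: int = 0
    n_duplicates: int = 0
    n_outside_extent: int = 0
    n_off_land: int = 0
    n_outside_years: int = 0
    n_retained: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(vars(self)), "count": list(vars(self).values())}
        )


def clean_occurrences(
    raw: pd.DataFrame,
    extent: tuple[float, float, float, float],
    year_range: tuple[int, int] = (2014, 2024),
    land: Raster | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Deduplicate, clip to extent/land, and apply the temporal filter.

    ``land`` (optional) is a raster whose positive, unmasked cells count as
    land; records falling on sea or masked cells are dropped.  Returns the
    cleaned table and a per-stage :class:`FilterReport`.  An empty result is
    a warning, not an error.
    """
    if raw.empty:
        raise ValueError("raw occurrence table is empty")
    missing = set(OCCURRENCE_COLUMNS) - set(raw.columns)
    if missing:
        raise KeyError(f"occurrence table missing columns: {sorted(missing)}")
    rep = FilterReport(n_input=len(raw))

    df = raw.drop_duplicates(subset=["species", "lon", "lat"]).copy()
    rep.n_duplicates = rep.n_input - len(df)

    lon_min, lon_max, lat_min, lat_max = extent
    inside = (
        (df["lon"] >= lon_min)
        & (df["lon"] <= lon_max)
        & (df["lat"] >= lat_min)
        & (df["lat"] <= lat_max)
    )
    rep.n_outside_extent = int((~inside).sum())
    df = df[inside]

    if land is not None and len(df):
        row, col = land.grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        ok = (row >= 0) & (col >= 0)
        on_land = ok.copy()
        on_land[ok] = (land.values[row[ok], col[ok]] > 0) & ~land.mask[row[ok], col[ok]]
        rep.n_off_land = int((~on_land).sum())
        df = df[on_land]

    in_years = (df["year"] >= year_range[0]) & (df["year"] <= year_range[1])
    rep.n_outside_years = int((~in_years).sum())
    df = df[in_years].reset_index(drop=True)

    rep.n_retained = len(df)
    if not len(df):
        warnings.warn("no occurrence records survived cleaning", stacklevel=2)
    return df, rep


def thin_occurrences(table: pd.DataFrame, cell_size_km: float = 1.0) -> pd.DataFrame:
    """Keep at most one record per ``cell_size_km`` cell of a local metric grid.

    The metric grid scales longitude by cos(latitude); at 1-km scale this is
    indistinguishable from a projected grid.  Within a cell the retained
    record is the lexicographic minimum of (year, lon, lat) — a deterministic,
    seed-free tie-break, so thinning an already-thinned table is a no-op.
    """
    if table.empty:
        return table.copy()
    df = table.copy()
    y_km = df["lat"].to_numpy() * KM_PER_DEG
    x_km = df["lon"].to_numpy() * KM_PER_DEG * np.cos(np.deg2rad(df["lat"].to_numpy()))
    df["_cy"] = np.floor(y_km / cell_size_km).astype(int)
    df["_cx"] = np.floor(x_km / cell_size_km).astype(int)
    df = df.sort_values(["year", "lon", "lat"], kind="mergesort")
    df = df.drop_duplicates(subset=["species", "_cy", "_cx"], keep="first")
    return (
        df.drop(columns=["_cy", "_cx"])
        .sort_index()
        .reset_index(drop=True)
    )


def aggregate_to_grid(
    table: pd.DataFrame, grid: GridSpec, valid_mask: np.ndarray | None = None
) -> np.ndarray:
    """Unique presence cells (flat row-major indices) containing >= 1 record.

    Points on a masked or out-of-grid cell are dropped with a warning.  Edge
    points follow the half-open [edge, edge + resolution) convention of
    :meth:`GridSpec.cell_of`.
    """
    row, col = grid.cell_of(table["lon"].to_numpy(), table["lat"].to_numpy())
    ok = (row >= 0) & (col >= 0)
    if valid_mask is not None:
        ok2 = ok.copy()
        ok2[ok] = valid_mask[row[ok], col[ok]]
        ok = ok2
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} occurrence record(s) fell on masked or out-of-grid cells",
            stacklevel=2,
        )
    flat = row[ok] * grid.n_cols + col[ok]
    return np.unique(flat)


def coastal_buffer_mask(
    grid: GridSpec, coast: Raster, distance_km: float = 200.0
) -> Raster:
    """Boolean raster: cell centers within ``distance_km`` of any coast cell.

    Distance is great-circle (haversine) between cell centers; a coast cell is
    at distance zero and always included.  Coast cells are the cells of
    ``coast`` with value 2 (see :mod:`ensdm.simulate`), or any positive cell
    if no value-2 cells exist (so a plain binary coastline raster works too).
    """
    ci, cj = np.nonzero(coast.values == 2.0)
    if ci.size == 0:
        ci, cj = np.nonzero((coast.values > 0) & ~coast.mask)
    if ci.size == 0:
        raise ValueError("coast raster has no coast cells")
    lonc = grid.lon_centers()
    latc = grid.lat_centers()
    coast_lon = lonc[cj]
    coast_lat = latc[ci]
    within = np.zeros(grid.shape, dtype=bool)
    # row-by-row broadcast keeps memory at n_cols x n_coast
    for i in range(grid.n_rows):
        d = haversine_km(
            lonc[:, None], np.full((grid.n_cols, 1), latc[i]), coast_lon[None, :], coast_lat[None, :]
        )
        within[i] = (d <= distance_km).any(axis=1)
    return Raster(grid, within.astype(float), np.zeros(grid.shape, dtype=bool))


def sample_pseudo_absences(
    valid_mask: np.ndarray,
    presence_cells: np.ndarray,
    grid: GridSpec,
    ratio: int = 2,
    background: str = "full-domain",
    buffer_mask: Raster | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``ratio x n_presences`` background cells uniformly without replacement.

    ``background`` is "full-domain" (every valid cell) or "coastal-buffer"
    (valid cells inside ``buffer_mask``).  Presence cells are excluded from
    the pool so no cell carries both labels.  Raises with the exact shortfall
    if the pool is too small.
    """
    if background not in ("full-domain", "coastal-buffer"):
        raise ValueError(f"unknown background {background!r}")
    eligible = valid_mask.copy()
    if background == "coastal-buffer":
        if buffer_mask is None:
            raise ValueError("coastal-buffer background requires buffer_mask")
        eligible &= buffer_mask.values > 0
    flat_eligible = np.flatnonzero(eligible.ravel())
    flat_eligible = np.setdiff1d(flat_eligible, presence_cells, assume_unique=False)
    n_needed = ratio * presence_cells.size
    if flat_eligible.size < n_needed:
        raise ValueError(
            f"need {n_needed} pseudo-absence cells but only {flat_eligible.size} "
            f"eligible cells in the {background} background "
            f"(shortfall {n_needed - flat_eligible.size})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat_eligible, size=n_needed, replace=False)
    return np.sort(chosen)


def build_training_table(
    presence_cells: np.ndarray,
    absence_cells: np.ndarray,
    stack: PredictorStack,
) -> pd.DataFrame:
    """Label cells and extract the predictor values into a model-ready table.

    Columns: ``label`` (1 presence, 0 pseudo-absence), ``cell`` (flat grid
    index), then one column per predictor.  Rows with any missing predictor
    are discarded (and counted in a warning).  Presence and absence cells must
    be disjoint.
    """
    overlap = np.intersect1d(presence_cells, absence_cells)
    if overlap.size:
        raise ValueError(f"{overlap.size} cell(s) appear as both presence and absence")
    cells = np.concatenate([presence_cells, absence_cells]).astype(int)
    labels = np.concatenate(
        [np.ones(presence_cells.size, dtype=int), np.zeros(absence_cells.size, dtype=int)]
    )
    rows, cols = np.divmod(cells, stack.grid.n_cols)
    X = stack.extract(rows, cols)
    df = pd.DataFrame(X, columns=stack.names)
    df.insert(0, "cell", cells)
    df.insert(0, "label", labels)
    complete = ~df[stack.names].isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"discarded {n_dropped} row(s) with missing predictor values", stacklevel=2
        )
    out = df[complete].reset_index(drop=True)
    if out.empty:
        raise ValueError("all training rows had missing predictor values")
    return out
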