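"""Synthetic landscapes and virtual species.

The generator stands in for the study system that real occurrence archives
and climate/land-use rasters would provide: spatially autocorrelated climate
analogs (annual mean temperature BIO1, temperature seasonality BIO4, annual
precipitation BIO12, precipitation seasonality BIO15), fractional land-use
layers (Urban/Crop/Pasture in percent, with urbanization concentrated near a
simulated coast), a coastline for the 200-km accessible-area buffer, a
virtual species with a known response to each predictor, presence-only
sampling proportional to true suitability, and affine "warming / land-use
trend" scenario perturbations.  Because the true suitability surface is
known, the whole downstream pipeline can be validated against ground truth.

Autocorrelated fields are built by Gaussian-kernel smoothing of seeded white
noise; the smoothing length (in cells) is the autocorrelation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import GridSpec, PredictorStack, Raster, PREDICTOR_NAMES

#: default synthetic study window (matches the occurrence temporal filter)
YEAR_RANGE = (2014, 2024)

# land/coast codes used by simulate_coastline
SEA, LAND, COAST = 0.0, 1.0, 2.0


def _smooth_field(shape: tuple[int, int], correlation_length: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance smoothed Gaussian white noise."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=correlation_length, mode="reflect")
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_coastline(grid: GridSpec, seed: int = 0) -> Raster:
    """A binary land/coast mask with the sea along the eastern margin.

    Values: 0 = sea, 1 = land interior, 2 = coast (the easternmost land cell
    in each row).  The coastline meanders with latitude; coast cells are a
    subset of land cells, one per row.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = grid.shape
    # boundary column per row: smooth wander near the eastern edge
    wander = gaussian_filter(rng.standard_normal(n_rows), sigma=max(2, n_rows // 20), mode="reflect")
    if wander.std() > 1e-12:
        wander = wander / wander.std()
    margin = max(2, n_cols // 10)
    boundary = np.clip(
        (n_cols - margin + wander * (margin / 2.0)).astype(int), n_cols // 2, n_cols - 1
    )
    values = np.zeros(grid.shape)
    for i in range(n_rows):
        values[i, : boundary[i] + 1] = LAND
        values[i, boundary[i]] = COAST
    return Raster(grid, values, np.zeros(grid.shape, dtype=bool))


def land_mask(coast_raster: Raster) -> np.ndarray:
    return coast_raster.values >= LAND


def coast_cells(coast_raster: Raster) -> tuple[np.ndarray, np.ndarray]:
    return np.nonzero(coast_raster.values == COAST)


def simulate_predictor_stack(
    grid: GridSpec,
    correlation_length: float = 8.0,
    seed: int = 0,
    coast: Raster | None = None,
) -> PredictorStack:
    """Simulate the seven-predictor stack on ``grid``.

    BIO1 combines a north-to-south latitudinal warming gradient with a
    smoothed random field; BIO4/BIO12/BIO15 are independent smoothed fields
    scaled to realistic magnitudes; Urban/Crop/Pasture are logistic-squashed
    fields scaled to percent, with Urban intensity decaying away from the
    simulated coast.  Cells that are sea on the coast raster are masked in
    every layer, so the stack's valid mask equals the land mask.
    """
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ValueError("grid too small to simulate (need at least 3x3)")
    if correlation_length < 1:
        raise ValueError("correlation_length must be >= 1 cell")
    if coast is None:
        coast = simulate_coastline(grid, seed=seed)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    shape = grid.shape
    lat = grid.lat_centers()[:, None] * np.ones((1, grid.n_cols))
    lat01 = (grid.lat_max - lat) / (grid.lat_max - grid.lat_min)  # 0 north -> 1 south

    def f(i: int) -> np.ndarray:
        return _smooth_field(shape, correlation_length, np.random.default_rng(int(seeds[i])))

    # climate analogs (units: degC, degC, mm, mm)
    bio1 = 2.0 + 22.0 * lat01 + 2.5 * f(0)
    bio4 = 800.0 - 450.0 * lat01 + 120.0 * f(1)
    bio12 = np.clip(250.0 + 1500.0 * lat01 + 350.0 * f(2), 0.0, None)
    bio15 = np.clip(70.0 + 25.0 * f(3), 0.0, None)

    # distance (in columns) to the coast column of each row, for the urban gradient
    col = np.arange(grid.n_cols)[None, :] * np.ones((grid.n_rows, 1))
    coast_col = np.full((grid.n_rows, 1), grid.n_cols - 1, dtype=float)
    ci, cj = coast_cells(coast)
    coast_col[ci, 0] = cj
    dist_coast = np.abs(coast_col - col) / max(1, grid.n_cols)

    urban = 100.0 * _logistic(1.2 * f(4) - 6.0 * dist_coast + 0.5)
    crop = 100.0 * _logistic(1.0 * f(5) - 0.8)
    pasture = 100.0 * _logistic(1.0 * f(6) - 1.2)

    sea = ~land_mask(coast)
    stack = PredictorStack(grid)
    for name, vals in zip(
        PREDICTOR_NAMES, (bio1, bio4, bio12, bio15, urban, crop, pasture)
    ):
        stack.add_layer(name, Raster(grid, vals, sea.copy()))
    return stack


# ---------------------------------------------------------------------------
# virtual species


@dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped response: exp(-(x - optimum)^2 / (2 breadth^2))."""

    optimum: float
    breadth: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((x - self.optimum) / self.breadth) ** 2)


@dataclass(frozen=True)
class LogisticResponse:
    """Sigmoid response: 1/(1 + exp(-slope (x - midpoint))).  Negative slope declines."""

    midpoint: float
    slope: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _logistic(self.slope * (x - self.midpoint))


@dataclass(frozen=True)
class LinearResponse:
    """Ramp from 0 at ``low`` to 1 at ``high``, clipped outside."""

    low: float
    high: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.clip((x - self.low) / (self.high - self.low), 0.0, 1.0)


@dataclass
class VirtualSpecies:
    """A simulated taxon with a known environmental response.

    ``true_suitability`` is the cellwise combination (product or geometric
    mean) of the per-predictor response curves evaluated on the stack; it is
    the ground truth that fitted models are judged against.
    """

    name: str
    responses: dict[str, object]
    combination: str
    true_suitability: Raster


def make_virtual_species(
    stack: PredictorStack,
    responses: dict[str, object],
    combination: str = "geometric",
    name: str = "virtual",
) -> VirtualSpecies:
    """Evaluate response curves on the stack and combine them into suitability.

    ``combination``: "product" multiplies the factors (a single zero factor
    annihilates suitability); "geometric" takes the geometric mean, which
    keeps the combined surface on a comparable scale as factors are added.
    """
    if combination not in ("product", "geometric"):
        raise ValueError(f"unknown combination {combination!r}")
    valid = stack.valid_mask
    if not valid.any():
        raise ValueError("predictor stack has an empty valid mask")
    unknown = set(responses) - set(stack.names)
    if unknown:
        raise KeyError(f"responses reference unknown predictors: {sorted(unknown)}")

    factors = []
    for pname, fn in responses.items():
        layer = stack.layers[pname]
        factors.append(np.clip(fn(layer.values), 0.0, 1.0))
    if not factors:
        suit = np.ones(stack.grid.shape)
    elif combination == "product":
        suit = np.prod(factors, axis=0)
    else:
        stacked = np.clip(np.stack(factors), 1e-300, 1.0)
        suit = np.exp(np.mean(np.log(stacked), axis=0))
        suit[np.any(np.stack(factors) == 0.0, axis=0)] = 0.0
    return VirtualSpecies(name, dict(responses), combination, Raster(stack.grid, suit, ~valid))


def sample_presences(
    species: VirtualSpecies,
    n: int,
    seed: int = 0,
    year_range: tuple[int, int] = YEAR_RANGE,
) -> pd.DataFrame:
    """Draw presence-only records with detection proportional to suitability.

    Cells are sampled without replacement with probability proportional to
    true suitability (a simple model of opportunistic, abundance-weighted
    recording); point coordinates are jittered uniformly within the chosen
    cell and years drawn uniformly from ``year_range``.  Returns an
    occurrence table (species, lon, lat, year).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = species.true_suitability
    rows, cols = np.nonzero(suit.valid & (suit.values > 0))
    if rows.size < n:
        raise ValueError(
            f"requested {n} presences but only {rows.size} cells have positive suitability"
        )
    w = suit.values[rows, cols]
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False, p=w / w.sum())
    g = suit.grid
    lon = g.lon_min + (cols[idx] + rng.uniform(0, 1, size=n)) * g.resolution
    lat = g.lat_max - (rows[idx] + rng.uniform(0, 1, size=n)) * g.resolution
    year = rng.integers(year_range[0], year_range[1] + 1, size=n)
    return pd.DataFrame(
        {"species": species.name, "lon": lon, "lat": lat, "year": year}
    )


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    """An affine perturbation of the baseline stack.

    temperature_offset is added to BIO1 (degC); precipitation_scale multiplies
    BIO12; landuse_trend adds percentage points per land-use class (clipped
    back to [0, 100]).  This exercises the projection machinery without
    claiming to emulate any climate model's spatial pattern.
    """

    name: str
    temperature_offset: float = 0.0
    precipitation_scale: float = 1.0
    landuse_trend: tuple[tuple[str, float], ...] = ()
    horizon: str = ""


def perturb_scenario(stack: PredictorStack, spec: ScenarioSpec) -> PredictorStack:
    """Apply a :class:`ScenarioSpec` to a baseline stack; masks are unchanged."""
    out = stack.copy()
    out.layers["BIO1"].values += spec.temperature_offset
    out.layers["BIO12"].values *= spec.precipitation_scale
    for lname, delta in spec.landuse_trend:
        if lname not in out.layers:
            raise KeyError(f"landuse_trend names unknown layer {lname!r}")
        layer = out.layers[lname]
        layer.values += delta
        np.clip(layer.values, 0.0, 100.0, out=layer.values)
    return out


def default_inland_species(stack: PredictorStack) -> VirtualSpecies:
    """A warm, humid, low-agriculture inland taxon (strong climate signal)."""
    return make_virtual_species(
        stack,
        {
            "BIO1": GaussianResponse(optimum=22.0, breadth=1.2),
            "BIO12": LogisticResponse(midpoint=1500.0, slope=0.015),
            "Crop": LogisticResponse(midpoint=55.0, slope=-0.15),
        },
        combination="product",
        name="inland_virtual",
    )


def default_coastal_species(stack: PredictorStack) -> VirtualSpecies:
    """A warm coastal-estuarine taxon tracking the urbanized coastal fringe."""
    return make_virtual_species(
        stack,
        {
            "BIO1": GaussianResponse(optimum=22.0, breadth=2.0),
            "Urban": LogisticResponse(midpoint=45.0, slope=0.5),
            "BIO15": GaussianResponse(optimum=70.0, breadth=18.0),
        },
        combination="product",
        name="coastal_virtual",
    )
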