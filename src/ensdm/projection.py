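"""Scenario projection, suitability summaries, and area accounting.

A fitted ensemble is projected onto a scenario predictor stack to give a
continuous suitability surface; the baseline-derived ensemble P10 threshold
(a property of the calibration presences, which have no future analog)
binarizes it, unless per-scenario recomputation is requested.  Summaries
are the mean, median, and 95th percentile of suitability over valid cells;
areas are reported above the fixed thresholds 0.3/0.5/0.7 and above P10,
with the net change (scenario minus baseline, negative = net loss) and a
four-class change map whose gain/loss areas reconcile exactly with the net
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import EnsembleSDM, binarize, p10_threshold, suitable_area
from .grids import PredictorStack, Raster

FIXED_THRESHOLDS = (0.3, 0.5, 0.7)

#: change-map legend
CHANGE_CLASSES = {
    0: "stable-unsuitable",
    1: "gain",
    2: "loss",
    3: "stable-suitable",
}


def suitability_summary(surface: Raster) -> tuple[float, float, float]:
    """(mean, median, 95th percentile) of suitability over valid cells."""
    v = surface.valid_values()
    if v.size == 0:
        raise ValueError("surface has no valid cells")
    return (
        float(v.mean()),
        float(np.quantile(v, 0.5, method="linear")),
        float(np.quantile(v, 0.95, method="linear")),
    )


def area_above_thresholds(
    surface: Raster, areas: Raster, thresholds: tuple[float, ...] = FIXED_THRESHOLDS
) -> dict[float, float]:
    """km² with suitability >= each threshold; non-increasing in the threshold."""
    out = {}
    for t in thresholds:
        out[t] = suitable_area(binarize(surface, t), areas)
    return out


def area_change(baseline_km2: float, scenario_km2: float) -> float:
    """Net change in suitable area, scenario minus baseline (negative = loss)."""
    if baseline_km2 < 0 or scenario_km2 < 0:
        raise ValueError("areas must be non-negative")
    return scenario_km2 - baseline_km2


def change_map(binary_baseline: Raster, binary_scenario: Raster) -> Raster:
    """Cellwise 2x2 classification of binary suitability change.

    Codes per :data:`CHANGE_CLASSES`; the area of gain cells minus the area
    of loss cells equals the net area change exactly.
    """
    if binary_baseline.grid != binary_scenario.grid:
        raise ValueError("baseline and scenario maps are on different grids")
    b = binary_baseline.values == 1.0
    s = binary_scenario.values == 1.0
    codes = np.where(b & s, 3.0, np.where(~b & s, 1.0, np.where(b & ~s, 2.0, 0.0)))
    mask = binary_baseline.mask | binary_scenario.mask
    codes = np.where(mask, np.nan, codes)
    return Raster(binary_baseline.grid, codes, mask)


@dataclass
class ScenarioResult:
    """Everything the scenario tables report for one projection."""

    scenario: str
    surface: Raster
    binary: Raster
    threshold: float
    mean: float
    median: float
    p95: float
    fixed_areas: dict[float, float]
    p10_area_km2: float
    baseline_area_km2: float | None = None

    @property
    def delta_km2(self) -> float | None:
        if self.baseline_area_km2 is None:
            return None
        return area_change(self.baseline_area_km2, self.p10_area_km2)

    def summary_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "mean_suitability": self.mean,
            "median_suitability": self.median,
            "p95_suitability": self.p95,
            **{f"area_ge_{t}_km2": a for t, a in self.fixed_areas.items()},
            "p10_area_km2": self.p10_area_km2,
        }
        if self.baseline_area_km2 is not None:
            row["delta_km2"] = self.delta_km2
        return row


def project_scenario(
    ensemble: EnsembleSDM,
    scenario_stack: PredictorStack,
    areas: Raster,
    scenario: str = "scenario",
    baseline_area_km2: float | None = None,
    thresholds: tuple[float, ...] = FIXED_THRESHOLDS,
    rederive_p10: bool = False,
    presence_X=None,
) -> ScenarioResult:
    """Project an ensemble onto a scenario stack and attach all summaries.

    The binary map uses the ensemble's baseline P10 by default; with
    ``rederive_p10=True`` (and ``presence_X`` given) the threshold is
    recomputed from the scenario predictions at the calibration presences.
    """
    surface = ensemble.predict_surface(scenario_stack)
    threshold = ensemble.p10
    if rederive_p10:
        if presence_X is None:
            raise ValueError("rederive_p10 requires presence_X")
        threshold = p10_threshold(ensemble.predict(presence_X))
    binary = binarize(surface, threshold)
    mean, median, p95 = suitability_summary(surface)
    return ScenarioResult(
        scenario=scenario,
        surface=surface,
        binary=binary,
        threshold=threshold,
        mean=mean,
        median=median,
        p95=p95,
        fixed_areas=area_above_thresholds(surface, areas, thresholds),
        p10_area_km2=suitable_area(binary, areas),
        baseline_area_km2=baseline_area_km2,
    )


def scenario_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """One row per scenario, mirroring the suitability/area report tables."""
    return pd.DataFrame([r.summary_row() for r in results])
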