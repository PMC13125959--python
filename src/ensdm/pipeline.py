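"""End-to-end orchestration of the ensemble SDM workflow.

``RunConfig`` collects every stage's parameters (grid, simulation or input
paths, background design, model settings, CV, gates, thresholds, scenarios)
and serializes into the run manifest so a run can be reproduced.  A single
master seed is declared; each stage derives its own seed by hashing
``"{master}:{stage}"``, so adding a stage never perturbs the randomness of
earlier stages.  ``run_pipeline`` executes simulate -> clean/thin ->
background -> fit -> cross-validate -> gate/ensemble -> interpret ->
project -> report, writing CSV/GeoTIFF artifacts plus a JSON manifest with
content hashes, and returns the in-memory results for library use.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import evaluation as ev
from . import interpret as itp
from . import models as md
from . import occurrences as occ
from . import projection as prj
from . import simulate as sim
from .geotiff import write_geotiff
from .grids import PREDICTOR_NAMES, cell_area_raster, make_grid

log = logging.getLogger("ensdm")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by hashing."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class FamilyConfig:
    """Per-family sampling design (background type and presence count)."""

    name: str = "inland"
    kind: str = "inland"  # "inland" or "coastal" virtual species
    n_presences: int = 300
    background: str = "full-domain"  # or "coastal-buffer"
    buffer_km: float = 200.0
    pa_ratio: int = 2


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    extent: tuple[float, float, float, float] = (110.0, 120.0, 20.0, 30.0)
    resolution: float = 0.1
    correlation_length: float = 8.0
    seed: int = 0
    year_range: tuple[int, int] = (2014, 2024)
    families: list[FamilyConfig] = field(default_factory=lambda: [FamilyConfig()])
    n_trees: int = 500
    hinge_knots: int = 10
    penalty_path: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    cv_folds: int = 5
    auc_min: float = ens.AUC_GATE
    tss_min: float = ens.TSS_GATE
    fixed_thresholds: tuple[float, ...] = prj.FIXED_THRESHOLDS
    shap_sample: int = 40
    importance_reps: int = 10
    scenarios: list[sim.ScenarioSpec] = field(
        default_factory=lambda: [
            sim.ScenarioSpec("ssp_low", 1.5, 1.05, (("Crop", 5.0),), "2050s"),
            sim.ScenarioSpec("ssp_high", 3.5, 0.95, (("Crop", 15.0), ("Urban", 5.0)), "2050s"),
        ]
    )
    output_dir: str = "ensdm_run"
    write_rasters: bool = True

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fams = [FamilyConfig(**f) for f in raw.pop("families", [])]
        scens = [sim.ScenarioSpec(**_tupled(s)) for s in raw.pop("scenarios", [])]
        cfg = RunConfig(**raw)
        if fams:
            cfg.families = fams
        if scens:
            cfg.scenarios = scens
        return cfg


def _tupled(s: dict) -> dict:
    s = dict(s)
    if "landuse_trend" in s:
        s["landuse_trend"] = tuple((k, float(v)) for k, v in s["landuse_trend"])
    return s


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns results and writes a manifest.

    The returned dict maps family name to a dict holding the training table,
    member CV metrics, ensemble, interpretation summaries, and per-scenario
    results; ``"manifest"`` holds the manifest written to the output dir.
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        df.to_csv(p, index=False)
        artifacts.append(p)

    def save_tif(raster, name: str) -> None:
        if config.write_rasters:
            p = out_dir / name
            write_geotiff(raster, p)
            artifacts.append(p)

    grid = make_grid(config.extent, config.resolution)
    coast = sim.simulate_coastline(grid, seed=stage_seed(config.seed, "coast"))
    stack = sim.simulate_predictor_stack(
        grid,
        correlation_length=config.correlation_length,
        seed=stage_seed(config.seed, "stack"),
        coast=coast,
    )
    areas = cell_area_raster(grid)
    log.info("simulated %dx%d stack, %d valid cells", *grid.shape, stack.valid_mask.sum())
    for name, layer in stack.layers.items():
        save_tif(layer, f"predictor_{name}.tif")

    results: dict = {"grid": grid, "stack": stack, "coast": coast}
    for fam in config.families:
        fam_seed = stage_seed(config.seed, f"family:{fam.name}")
        species = (
            sim.default_coastal_species(stack)
            if fam.kind == "coastal"
            else sim.default_inland_species(stack)
        )
        raw = sim.sample_presences(
            species, fam.n_presences, seed=fam_seed, year_range=config.year_range
        )
        raw["species"] = fam.name
        cleaned, report = occ.clean_occurrences(
            raw, config.extent, year_range=config.year_range, land=coast
        )
        thinned = occ.thin_occurrences(cleaned)
        presence_cells = occ.aggregate_to_grid(thinned, grid, stack.valid_mask)
        log.info(
            "%s: %d raw -> %d cleaned -> %d thinned -> %d presence cells",
            fam.name, len(raw), len(cleaned), len(thinned), presence_cells.size,
        )
        buffer_mask = None
        if fam.background == "coastal-buffer":
            buffer_mask = occ.coastal_buffer_mask(grid, coast, fam.buffer_km)
        absence_cells = occ.sample_pseudo_absences(
            stack.valid_mask,
            presence_cells,
            grid,
            ratio=fam.pa_ratio,
            background=fam.background,
            buffer_mask=buffer_mask,
            seed=stage_seed(config.seed, f"background:{fam.name}"),
        )
        train = occ.build_training_table(presence_cells, absence_cells, stack)
        save_csv(thinned, f"{fam.name}_occurrences.csv")
        save_csv(report.as_frame(), f"{fam.name}_filter_report.csv")
        save_csv(train, f"{fam.name}_training.csv")

        corr, vif = itp.collinearity_screen(train)
        save_csv(vif.rename_axis("predictor").reset_index(), f"{fam.name}_vif.csv")

        names = list(PREDICTOR_NAMES)
        fit_seed = stage_seed(config.seed, f"fit:{fam.name}")

        def fit_mx(tbl, s):
            return md.fit_maxent(
                tbl, names, md.FeatureSpec(hinge_knots=config.hinge_knots),
                penalty_path=config.penalty_path, seed=s,
            )

        def fit_rf(tbl, s):
            return md.fit_forest(tbl, names, n_trees=config.n_trees, seed=s)

        cv_mx = ev.cross_validate(fit_mx, train, k=config.cv_folds, seed=fit_seed, algorithm="maxent-style")
        cv_rf = ev.cross_validate(fit_rf, train, k=config.cv_folds, seed=fit_seed, algorithm="forest")
        model_mx = fit_mx(train, fit_seed)
        model_rf = fit_rf(train, fit_seed + 1)
        save_csv(pd.concat([cv_mx.as_frame(), cv_rf.as_frame()]), f"{fam.name}_cv_metrics.csv")

        presence_X = train.loc[train["label"] == 1, names]
        ensemble = ens.build_ensemble(
            [model_mx, model_rf], [cv_mx, cv_rf], presence_X,
            auc_min=config.auc_min, tss_min=config.tss_min,
        )
        save_csv(ensemble.describe().assign(p10_ensemble=ensemble.p10), f"{fam.name}_ensemble.csv")

        imp_seed = stage_seed(config.seed, f"interpret:{fam.name}")
        importance = itp.permutation_importance(
            ensemble, train, n_reps=config.importance_reps, seed=imp_seed
        )
        rng = np.random.default_rng(imp_seed)
        sub = train.sample(
            n=min(config.shap_sample, len(train)), random_state=int(rng.integers(2**31 - 1))
        )
        phi, base = itp.shap_values(ensemble, sub, sub, predictor_names=names)
        shap_sum = itp.shap_summary(phi, names)
        pdps = {n: itp.partial_dependence(ensemble, n, train) for n in names}
        save_csv(importance, f"{fam.name}_permutation_importance.csv")
        save_csv(shap_sum, f"{fam.name}_shap_summary.csv")
        save_csv(
            pd.concat(
                [c.as_frame().rename(columns={n: "value"}).assign(predictor=n) for n, c in pdps.items()]
            ),
            f"{fam.name}_pdp.csv",
        )

        baseline = prj.project_scenario(
            ensemble, stack, areas, scenario="baseline",
            thresholds=config.fixed_thresholds,
        )
        save_tif(baseline.surface, f"{fam.name}_suitability_baseline.tif")
        save_tif(baseline.binary, f"{fam.name}_binary_baseline.tif")
        scen_results = [baseline]
        for spec in config.scenarios:
            scen_stack = sim.perturb_scenario(stack, spec)
            res = prj.project_scenario(
                ensemble, scen_stack, areas,
                scenario=f"{spec.name}_{spec.horizon}" if spec.horizon else spec.name,
                baseline_area_km2=baseline.p10_area_km2,
                thresholds=config.fixed_thresholds,
            )
            cmap = prj.change_map(baseline.binary, res.binary)
            save_tif(res.surface, f"{fam.name}_suitability_{res.scenario}.tif")
            save_tif(cmap, f"{fam.name}_change_{res.scenario}.tif")
            scen_results.append(res)
        save_csv(prj.scenario_table(scen_results), f"{fam.name}_scenario_table.csv")

        results[fam.name] = {
            "species": species,
            "occurrences": thinned,
            "filter_report": report,
            "training": train,
            "cv": {"maxent-style": cv_mx, "forest": cv_rf},
            "models": {"maxent-style": model_mx, "forest": model_rf},
            "ensemble": ensemble,
            "vif": vif,
            "importance": importance,
            "shap": shap_sum,
            "pdp": pdps,
            "baseline": baseline,
            "scenarios": scen_results[1:],
        }

    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ["coast", "stack"]
            + [f"{p}:{f.name}" for f in config.families for p in ("family", "background", "fit", "interpret")]
        },
        "artifacts": {str(p.relative_to(out_dir)): _sha256(p) for p in artifacts},
        "runtime_s": round(time.time() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
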