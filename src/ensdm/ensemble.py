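"""Performance-gated, AUC-weighted model averaging and P10 thresholding.

Members enter the ensemble only if their mean cross-validated AUC >= 0.90
and TSS >= 0.70 (inclusive).  Weights are proportional to mean CV AUC and
sum to one.  The P10 threshold — the 10th percentile of predicted
suitability at the calibration presences, so that at least 90% of presences
are classified suitable — binarizes the continuous surface; binary maps
combined with the geodesic cell-area raster give suitable-habitat areas in
km².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CVMetrics
from .grids import PredictorStack, Raster
from .models import FittedSDM, predict_surface

AUC_GATE = 0.90
TSS_GATE = 0.70


def gate_members(
    cv_list: list[CVMetrics], auc_min: float = AUC_GATE, tss_min: float = TSS_GATE
) -> list[int]:
    """Indices of members whose mean CV AUC and TSS meet the (inclusive) gates."""
    if not cv_list:
        raise ValueError("no candidate members")
    keep = [
        i
        for i, cv in enumerate(cv_list)
        if cv.mean_auc >= auc_min and cv.mean_tss >= tss_min
    ]
    if not keep:
        table = "\n".join(
            f"  {cv.algorithm or i}: AUC={cv.mean_auc:.3f} TSS={cv.mean_tss:.3f}"
            for i, cv in enumerate(cv_list)
        )
        raise ValueError(
            f"no members passed the gate (AUC>={auc_min}, TSS>={tss_min}):\n{table}"
        )
    return keep


def ensemble_weights(mean_aucs: list[float]) -> np.ndarray:
    """w_i = AUC_i / sum_j AUC_j."""
    a = np.asarray(mean_aucs, dtype=float)
    if (a <= 0).any():
        raise ValueError("AUC weights require strictly positive AUCs")
    return a / a.sum()


def p10_threshold(values: np.ndarray) -> float:
    """P10: interpolated 10th percentile, capped so >= 90% of values pass.

    The linearly interpolated 0.10 quantile is the headline convention; it is
    capped at the largest order statistic that still leaves at least 90% of
    the calibration values at or above the threshold (for some n the plain
    interpolated quantile would retain slightly less).  The coverage
    guarantee — fraction of inputs >= threshold is >= 0.90 — is the binding
    contract.  Below 10 values the rule degrades to the empirical minimum
    with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no suitability values supplied")
    if v.size < 10:
        import warnings

        warnings.warn(
            f"P10 on only {v.size} values; using the empirical minimum", stacklevel=2
        )
        return float(v.min())
    q = float(np.quantile(v, 0.10, method="linear"))
    srt = np.sort(v)
    cap = float(srt[int(np.floor(0.1 * v.size))])
    return min(q, cap)


def binarize(surface: Raster, threshold: float) -> Raster:
    """Indicator raster: 1 where suitability >= threshold (inclusive), masks kept."""
    vals = np.where(surface.mask, np.nan, (surface.values >= threshold).astype(float))
    return Raster(surface.grid, vals, surface.mask.copy())


def suitable_area(binary: Raster, areas: Raster) -> float:
    """Total km² of cells equal to 1, excluding masked cells."""
    if binary.grid != areas.grid:
        raise ValueError("binary map and cell-area raster are on different grids")
    sel = (binary.values == 1.0) & ~binary.mask & ~areas.mask
    return float(areas.values[sel].sum())


@dataclass
class EnsembleSDM:
    """Gated members, AUC-proportional weights, and the ensemble P10."""

    members: list[FittedSDM]
    cv: list[CVMetrics]
    weights: np.ndarray
    member_p10s: list[float]
    p10: float

    def predict(self, X) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members])
        return np.asarray(self.weights) @ preds

    def predict_surface(self, stack: PredictorStack) -> Raster:
        surfaces = [predict_surface(m, stack) for m in self.members]
        out = np.zeros(stack.grid.shape)
        for w, s in zip(self.weights, surfaces):
            out += w * s.filled(0.0)
        mask = surfaces[0].mask
        out[mask] = np.nan
        return Raster(stack.grid, out, mask.copy())

    def describe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "algorithm": [m.algorithm for m in self.members],
                "mean_auc": [c.mean_auc for c in self.cv],
                "sd_auc": [c.sd_auc for c in self.cv],
                "mean_tss": [c.mean_tss for c in self.cv],
                "sd_tss": [c.sd_tss for c in self.cv],
                "weight": list(self.weights),
                "p10_member": self.member_p10s,
            }
        )


def build_ensemble(
    candidates: list[FittedSDM],
    cv_list: list[CVMetrics],
    presence_X: pd.DataFrame | np.ndarray,
    auc_min: float = AUC_GATE,
    tss_min: float = TSS_GATE,
) -> EnsembleSDM:
    """Gate candidates, weight the survivors by AUC, and derive P10 thresholds.

    ``presence_X`` holds the predictor values at the calibration presences;
    each retained member's own P10 comes from its predictions there, and the
    ensemble P10 is recomputed from the weighted ensemble predictions at the
    same presences.
    """
    keep = gate_members(cv_list, auc_min=auc_min, tss_min=tss_min)
    members = [candidates[i] for i in keep]
    cv = [cv_list[i] for i in keep]
    weights = ensemble_weights([c.mean_auc for c in cv])
    member_preds = [m.predict(presence_X) for m in members]
    member_p10s = [p10_threshold(p) for p in member_preds]
    ens_pred = weights @ np.stack(member_preds)
    ens_p10 = p10_threshold(ens_pred)
    return EnsembleSDM(
        members=members, cv=cv, weights=weights, member_p10s=member_p10s, p10=ens_p10
    )
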