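"""Cross-validation and discrimination metrics.

AUC is the Mann-Whitney probability that a random presence outscores a
random background point (ties counted 1/2), computed from average ranks.
TSS is sensitivity + specificity - 1 at the threshold maximizing Youden's J,
with candidate thresholds at midpoints between consecutive distinct scores
plus the two infinities; ties in J break toward the lower (more sensitive)
threshold.  Cross-validation is stratified k-fold (shuffled round-robin
within class, so per-class fold counts differ by at most one), with fold
metrics aggregated as mean +/- sample SD (ddof = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class CVMetrics:
    """Per-fold and aggregated AUC/TSS for one algorithm."""

    algorithm: str
    aucs: list[float]
    tsss: list[float]
    thresholds: list[float]

    @property
    def k(self) -> int:
        return len(self.aucs)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if self.k > 1 else 0.0

    @property
    def mean_tss(self) -> float:
        return float(np.mean(self.tsss))

    @property
    def sd_tss(self) -> float:
        return float(np.std(self.tsss, ddof=1)) if self.k > 1 else 0.0

    def as_frame(self) -> pd.DataFrame:
        """Fold-level rows plus a summary row, mirroring a performance table."""
        rows = [
            {"algorithm": self.algorithm, "fold": i + 1, "auc": a, "tss": t, "youden_threshold": th}
            for i, (a, t, th) in enumerate(zip(self.aucs, self.tsss, self.thresholds))
        ]
        rows.append(
            {
                "algorithm": self.algorithm,
                "fold": "mean±sd",
                "auc": f"{self.mean_auc:.3f}±{self.sd_auc:.3f}",
                "tss": f"{self.mean_tss:.3f}±{self.sd_tss:.3f}",
                "youden_threshold": "",
            }
        )
        return pd.DataFrame(rows)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) with per-class counts differing by <= 1."""
    labels = np.asarray(labels)
    folds = np.full(labels.shape[0], -1, dtype=int)
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} rows, fewer than k={k}")
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores, method="average")
    r_pos = float(ranks[labels == 1].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def tss_max_youden(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(TSS, threshold) maximizing sensitivity + specificity - 1.

    Classification rule: predicted presence iff score >= threshold.
    Candidates are midpoints between consecutive distinct scores plus -inf
    and +inf; among maximizers the lowest threshold (highest sensitivity)
    wins.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute TSS")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    # vectorized: for each candidate t, sens = P(score>=t | pos), spec = P(score<t | neg)
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    sens = 1.0 - np.searchsorted(pos_scores, candidates, side="left") / n_pos
    spec = np.searchsorted(neg_scores, candidates, side="left") / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the FIRST maximizer = lowest threshold
    return float(j[best]), float(candidates[best])


def cross_validate(
    fit_fn: Callable[[pd.DataFrame, int], object],
    train: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    algorithm: str = "",
) -> CVMetrics:
    """Stratified k-fold CV of a model-fitting function.

    ``fit_fn(table, seed) -> model`` where the model exposes
    ``predict(X) -> suitability``; per-fold fits get seeds derived from the
    master seed so results are reproducible and independent across folds.
    """
    labels = train["label"].to_numpy(dtype=int)
    folds = stratified_kfold(labels, k=k, seed=seed)
    predictor_names = [c for c in train.columns if c not in ("label", "cell")]
    aucs, tsss, thresholds = [], [], []
    for fold in range(k):
        test = folds == fold
        fold_seed = int((seed * 100003 + fold * 7919 + 1) % (2**31 - 1))
        try:
            model = fit_fn(train[~test].reset_index(drop=True), fold_seed)
        except Exception as exc:  # annotate with fold id, then re-raise
            raise RuntimeError(f"model fit failed on CV fold {fold}: {exc}") from exc
        scores = np.asarray(model.predict(train.loc[test, predictor_names]))
        aucs.append(roc_auc(scores, labels[test]))
        tss, thr = tss_max_youden(scores, labels[test])
        tsss.append(tss)
        thresholds.append(thr)
    return CVMetrics(algorithm=algorithm, aucs=aucs, tsss=tsss, thresholds=thresholds)
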