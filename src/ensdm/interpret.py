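"""Model interpretation: permutation importance, Shapley values, partial
dependence, and collinearity screening.

Permutation importance reports the mean drop in AUC when one predictor
column is shuffled (repeated, seed-derived).  Shapley values attribute each
prediction, on the 0-1 suitability scale, across predictors; with seven
predictors the 2^7 = 128 coalitions are enumerated exactly (marginalizing
withheld predictors over a background sample), so local accuracy — base
value plus contributions equals the prediction — holds to machine
precision.  A Monte-Carlo permutation estimator is available for larger
predictor sets.  Mean absolute Shapley values are classified as strong
(>= 0.05), moderate ([0.02, 0.05)), or weak (< 0.02) effects on the
suitability scale.  Partial dependence varies one predictor over its
observed range with the others held at their medians (means by option).
Collinearity screening reports pairwise Pearson correlations and variance
inflation factors VIF_j = 1/(1 - R²_j).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import roc_auc

SHAP_STRONG = 0.05
SHAP_MODERATE = 0.02


def permutation_importance(
    model,
    eval_table: pd.DataFrame,
    n_reps: int = 10,
    seed: int = 0,
    predictor_names: list[str] | None = None,
) -> pd.DataFrame:
    """Mean ΔAUC (baseline minus permuted) per predictor over ``n_reps`` shuffles."""
    if predictor_names is None:
        predictor_names = [c for c in eval_table.columns if c not in ("label", "cell")]
    labels = eval_table["label"].to_numpy(dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation table must contain both classes")
    X = eval_table[predictor_names].to_numpy(dtype=float)
    base_auc = roc_auc(np.asarray(model.predict(X)), labels)
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(predictor_names):
        drops = []
        for _ in range(n_reps):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            drops.append(base_auc - roc_auc(np.asarray(model.predict(Xp)), labels))
        rows.append({"predictor": name, "delta_auc": float(np.mean(drops)), "n_reps": n_reps})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shapley values


def _coalition_values(model, X_eval: np.ndarray, X_bg: np.ndarray) -> np.ndarray:
    """v[S, i] = E_b f(x_i with columns in S, b elsewhere) for all 2^p subsets."""
    n_eval, p = X_eval.shape
    n_bg = X_bg.shape[0]
    v = np.empty((1 << p, n_eval))
    big = np.tile(X_bg, (n_eval, 1))  # (n_eval*n_bg, p), eval-major blocks
    eval_rep = np.repeat(X_eval, n_bg, axis=0)
    for S in range(1 << p):
        if S == 0:
            preds = np.asarray(model.predict(X_bg))
            v[0, :] = preds.mean()
            continue
        members = [j for j in range(p) if S >> j & 1]
        Xs = big.copy()
        Xs[:, members] = eval_rep[:, members]
        preds = np.asarray(model.predict(Xs)).reshape(n_eval, n_bg)
        v[S, :] = preds.mean(axis=1)
    return v


def shap_values(
    model,
    background: pd.DataFrame | np.ndarray,
    eval_points: pd.DataFrame | np.ndarray,
    predictor_names: list[str] | None = None,
    method: str = "exact",
    n_mc: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-point, per-predictor Shapley contributions and the base value.

    Returns ``(phi, base)`` with ``phi`` of shape (n_eval, p); ``base`` is
    the mean model prediction over the background.  ``method='exact'``
    enumerates every coalition (the default — cheap at p <= 10 or so);
    ``method='montecarlo'`` averages marginal contributions over ``n_mc``
    random predictor permutations with paired background draws.
    """
    if isinstance(background, pd.DataFrame):
        if predictor_names is None:
            predictor_names = [c for c in background.columns if c not in ("label", "cell")]
        background = background[predictor_names].to_numpy(dtype=float)
    if isinstance(eval_points, pd.DataFrame):
        eval_points = eval_points[predictor_names].to_numpy(dtype=float)
    X_bg = np.asarray(background, dtype=float)
    X_eval = np.asarray(eval_points, dtype=float)
    if X_bg.size == 0:
        raise ValueError("background sample is empty")
    p = X_eval.shape[1]

    if method == "exact":
        v = _coalition_values(model, X_eval, X_bg)
        phi = np.zeros((X_eval.shape[0], p))
        fact = [math.factorial(i) for i in range(p + 1)]
        for S in range(1 << p):
            s = bin(S).count("1")
            w = fact[s] * fact[p - s - 1] / fact[p]
            for j in range(p):
                if S >> j & 1:
                    continue
                phi[:, j] += w * (v[S | (1 << j)] - v[S])
        return phi, float(v[0, 0])

    if method == "montecarlo":
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        rng = np.random.default_rng(seed)
        n_eval = X_eval.shape[0]
        phi = np.zeros((n_eval, p))
        base_acc = 0.0
        for _ in range(n_mc):
            order = rng.permutation(p)
            b = X_bg[rng.integers(X_bg.shape[0], size=n_eval)]
            current = b.copy()
            prev = np.asarray(model.predict(current))
            base_acc += prev.mean()
            for j in order:
                current[:, j] = X_eval[:, j]
                nxt = np.asarray(model.predict(current))
                phi[:, j] += nxt - prev
                prev = nxt
        return phi / n_mc, float(base_acc / n_mc)

    raise ValueError(f"unknown method {method!r}")


def classify_shap(mean_abs_shap: float) -> str:
    """Effect class from a mean |SHAP|: strong >= 0.05 > moderate >= 0.02 > weak."""
    if mean_abs_shap < 0:
        raise ValueError("mean absolute SHAP cannot be negative")
    if mean_abs_shap >= SHAP_STRONG:
        return "strong"
    if mean_abs_shap >= SHAP_MODERATE:
        return "moderate"
    return "weak"


def shap_summary(
    phi: np.ndarray, predictor_names: list[str]
) -> pd.DataFrame:
    """Global importance: mean |SHAP| per predictor with its effect class."""
    mean_abs = np.abs(phi).mean(axis=0)
    return pd.DataFrame(
        {
            "predictor": predictor_names,
            "mean_abs_shap": mean_abs,
            "effect": [classify_shap(v) for v in mean_abs],
        }
    ).sort_values("mean_abs_shap", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# partial dependence


@dataclass
class PDPCurve:
    """A one-dimensional partial dependence curve."""

    predictor: str
    grid: np.ndarray
    response: np.ndarray
    conditioning: str  # "median" or "mean"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.predictor: self.grid, "suitability": self.response})


def partial_dependence(
    model,
    predictor: str,
    reference_table: pd.DataFrame,
    n_grid: int = 50,
    conditioning: str = "median",
    predictor_names: list[str] | None = None,
) -> PDPCurve:
    """Response to one predictor with the others fixed at their reference value.

    The focal predictor sweeps ``n_grid`` equally spaced values across its
    observed range in ``reference_table``; the other predictors sit at their
    reference-table median (default) or mean.
    """
    if predictor_names is None:
        predictor_names = [c for c in reference_table.columns if c not in ("label", "cell")]
    if predictor not in predictor_names:
        raise KeyError(f"unknown predictor {predictor!r}")
    if conditioning not in ("median", "mean"):
        raise ValueError("conditioning must be 'median' or 'mean'")
    ref = reference_table[predictor_names]
    fixed = ref.median() if conditioning == "median" else ref.mean()
    lo, hi = ref[predictor].min(), ref[predictor].max()
    grid = np.linspace(lo, hi, n_grid)
    X = np.tile(fixed.to_numpy(dtype=float), (n_grid, 1))
    X[:, predictor_names.index(predictor)] = grid
    return PDPCurve(
        predictor=predictor,
        grid=grid,
        response=np.asarray(model.predict(X)),
        conditioning=conditioning,
    )


# ---------------------------------------------------------------------------
# collinearity


def collinearity_screen(
    X: pd.DataFrame | np.ndarray, predictor_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Pearson correlation matrix and per-predictor VIF.

    VIF_j = 1/(1 - R²_j) from the least-squares regression of predictor j on
    the other predictors (with intercept); a perfectly collinear column is
    reported as ``inf``.
    """
    if isinstance(X, pd.DataFrame):
        if predictor_names is None:
            predictor_names = [c for c in X.columns if c not in ("label", "cell")]
        X = X[predictor_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if predictor_names is None:
            predictor_names = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 rows")
    if (X.std(axis=0) < 1e-12).any():
        raise ValueError("constant predictor column")
    corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    vifs = []
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    corr_df = pd.DataFrame(corr, index=predictor_names, columns=predictor_names)
    return corr_df, pd.Series(vifs, index=predictor_names, name="vif")
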