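"""The two member models.

MaxEnt-style model: an L1-penalized logistic regression on an expanded
feature basis (linear, quadratic, pairwise-product, and forward/reverse
hinge features, all min-max scaled to [0, 1] with bounds frozen at training
time), whose linear predictor is mapped to suitability by the complementary
log-log transform s = 1 - exp(-exp(eta + c)).  The calibration constant c is
chosen so that the mean presence linear predictor maps to suitability tau
(default 0.5), the usual convention for cloglog MaxEnt output.  The penalty
strength is picked on an internal stratified validation split by held-out
log-likelihood.

Random forest: a 500-tree probability classifier with mtry = floor(sqrt(p));
suitability is the averaged per-tree class probability of the presence
class.

Both models implement ``predict(X) -> suitability in [0, 1]`` on a
predictor matrix in the canonical column order, and can be projected over a
:class:`~ensdm.grids.PredictorStack` in bounded-memory blocks.
"""

from __future__ import annotations

import math
import pickle
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .grids import PredictorStack, Raster


# ---------------------------------------------------------------------------
# feature expansion


@dataclass(frozen=True)
class FeatureSpec:
    """Which MaxEnt feature classes to expand, and the frozen training bounds.

    ``lower``/``upper`` are per-predictor min/max captured from the training
    table by :func:`fit_feature_bounds`; prediction-time expansion reuses them
    (values are clamped to the training range first), so there is no leakage
    and extrapolated inputs stay inside the basis's domain.
    """

    classes: tuple[str, ...] = ("linear", "quadratic", "product", "hinge")
    hinge_knots: int = 10
    predictor_names: tuple[str, ...] = ()
    lower: tuple[float, ...] = ()
    upper: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.classes) - {"linear", "quadratic", "product", "hinge"}
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")


def fit_feature_bounds(X: np.ndarray, names: list[str], spec: FeatureSpec) -> FeatureSpec:
    """Freeze per-predictor min/max from training data into the spec."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    const = hi - lo < 1e-12
    if const.any():
        warnings.warn(
            f"constant predictor(s) {list(np.asarray(names)[const])}: "
            "quadratic/hinge features for them will be dropped",
            stacklevel=2,
        )
    return replace(
        spec,
        predictor_names=tuple(names),
        lower=tuple(map(float, lo)),
        upper=tuple(map(float, hi)),
    )


def build_features(X: np.ndarray, spec: FeatureSpec) -> tuple[np.ndarray, list[str]]:
    """Expand a predictor matrix into the MaxEnt feature basis.

    For p predictors and k hinge knots per direction the full basis has
    p linear + p quadratic + p(p-1)/2 product + 2pk hinge columns (175 for
    p = 7, k = 10).  Constant predictors contribute their (constant) linear
    column only.  All columns lie in [0, 1] for inputs within the training
    bounds; inputs are clamped to those bounds first.
    """
    if not spec.lower:
        raise ValueError("FeatureSpec has no training bounds; call fit_feature_bounds")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(spec.predictor_names):
        raise ValueError("X shape does not match spec.predictor_names")
    if np.isnan(X).any():
        raise ValueError("missing values in predictor matrix")
    lo = np.asarray(spec.lower)
    hi = np.asarray(spec.upper)
    rng_ = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    Z = np.clip((np.clip(X, lo, hi) - lo) / rng_, 0.0, 1.0)  # scaled linear
    const = hi - lo < 1e-12

    cols: list[np.ndarray] = []
    names: list[str] = []
    p = Z.shape[1]
    if "linear" in spec.classes:
        for j in range(p):
            cols.append(Z[:, j])
            names.append(f"lin:{spec.predictor_names[j]}")
    if "quadratic" in spec.classes:
        for j in range(p):
            if const[j]:
                continue
            cols.append(Z[:, j] ** 2)
            names.append(f"quad:{spec.predictor_names[j]}")
    if "product" in spec.classes:
        for a in range(p):
            for b in range(a + 1, p):
                cols.append(Z[:, a] * Z[:, b])
                names.append(f"prod:{spec.predictor_names[a]}*{spec.predictor_names[b]}")
    if "hinge" in spec.classes:
        k = spec.hinge_knots
        for j in range(p):
            if const[j]:
                continue
            # forward hinges rise from knot t to 1 at the training max;
            # reverse hinges fall from 1 at the training min to 0 at knot t
            fwd_knots = np.arange(k) / k          # in scaled units, excludes 1
            rev_knots = (np.arange(k) + 1) / k    # excludes 0
            for t in fwd_knots:
                cols.append(np.clip((Z[:, j] - t) / (1.0 - t), 0.0, 1.0))
                names.append(f"hingef:{spec.predictor_names[j]}@{t:.3f}")
            for t in rev_knots:
                cols.append(np.clip((t - Z[:, j]) / t, 0.0, 1.0))
                names.append(f"hinger:{spec.predictor_names[j]}@{t:.3f}")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# fitted models


@dataclass
class FittedSDM:
    """A fitted member model exposing suitability prediction.

    ``algorithm`` is "maxent-style" or "forest".  ``predict`` takes a
    (n, p) predictor matrix in ``predictor_names`` order, or a DataFrame
    containing those columns, and returns suitability in [0, 1].
    """

    algorithm: str
    predictor_names: tuple[str, ...]
    n_presences: int
    n_absences: int
    seed: int
    feature_spec: FeatureSpec | None = None
    coef: np.ndarray | None = None
    intercept: float = 0.0
    cloglog_offset: float = 0.0
    penalty_C: float | None = None
    forest: RandomForestClassifier | None = None

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.predictor_names)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def linear_predictor(self, X) -> np.ndarray:
        if self.algorithm != "maxent-style":
            raise AttributeError("linear_predictor is defined for the maxent-style model")
        F, _ = build_features(self._matrix(X), self.feature_spec)
        return F @ self.coef + self.intercept

    def predict(self, X) -> np.ndarray:
        X = self._matrix(X)
        if self.algorithm == "maxent-style":
            eta = self.linear_predictor(X)
            return 1.0 - np.exp(-np.exp(np.clip(eta + self.cloglog_offset, -700, 30)))
        if self.algorithm == "forest":
            proba = self.forest.predict_proba(X)
            presence_col = int(np.flatnonzero(self.forest.classes_ == 1)[0])
            return proba[:, presence_col]
        raise ValueError(f"unknown algorithm {self.algorithm!r}")

    # serialization ---------------------------------------------------------
    def to_bytes(self) -> bytes:
        return pickle.dumps(self, protocol=pickle.HIGHEST_PROTOCOL)

    @staticmethod
    def from_bytes(blob: bytes) -> "FittedSDM":
        obj = pickle.loads(blob)
        if not isinstance(obj, FittedSDM):
            raise TypeError("blob does not contain a FittedSDM")
        return obj

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @staticmethod
    def load(path) -> "FittedSDM":
        with open(path, "rb") as fh:
            return FittedSDM.from_bytes(fh.read())


def _split_table(train: pd.DataFrame, predictor_names: list[str]):
    y = train["label"].to_numpy(dtype=int)
    X = train[predictor_names].to_numpy(dtype=float)
    return X, y


def fit_maxent(
    train: pd.DataFrame,
    predictor_names: list[str] | None = None,
    spec: FeatureSpec | None = None,
    penalty_path: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    tau: float = 0.5,
    seed: int = 0,
) -> FittedSDM:
    """Fit the MaxEnt-style penalized logistic model with cloglog output.

    ``penalty_path`` is a grid of inverse regularization strengths C; the
    value with the best held-out log-likelihood on an internal stratified
    80/20 split is refit on the full table.  The cloglog offset c solves
    1 - exp(-exp(mean(eta|presence) + c)) = tau.
    """
    if predictor_names is None:
        predictor_names = [c for c in train.columns if c not in ("label", "cell")]
    X, y = _split_table(train, predictor_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    n_pres = int((y == 1).sum())
    if n_pres < 20:
        warnings.warn(f"only {n_pres} presences; maxent-style fit may be unstable", stacklevel=2)
    if spec is None:
        spec = FeatureSpec()
    spec = fit_feature_bounds(X, predictor_names, spec)
    F, _ = build_features(X, spec)

    rng = np.random.default_rng(seed)
    # stratified 80/20 internal split for the penalty path
    val = np.zeros(len(y), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        val[idx[: max(1, len(idx) // 5)]] = True

    def fit_one(Fm, ym, C):
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", tol=1e-8, max_iter=5000,
            random_state=seed,
        ).fit(Fm, ym)

    best_C, best_ll = None, -np.inf
    if len(penalty_path) > 1 and val.sum() >= 2 and len(np.unique(y[~val])) == 2:
        for C in penalty_path:
            m = fit_one(F[~val], y[~val], C)
            p = np.clip(m.predict_proba(F[val])[:, 1], 1e-12, 1 - 1e-12)
            ll = float(np.sum(y[val] * np.log(p) + (1 - y[val]) * np.log(1 - p)))
            if ll > best_ll:
                best_ll, best_C = ll, C
    else:
        best_C = penalty_path[0]

    model = fit_one(F, y, best_C)
    coef = model.coef_.ravel()
    intercept = float(model.intercept_[0])
    eta_pres = F[y == 1] @ coef + intercept
    # c such that cloglog(mean presence eta + c) = tau
    c = math.log(-math.log(1.0 - tau)) - float(eta_pres.mean())
    return FittedSDM(
        algorithm="maxent-style",
        predictor_names=tuple(predictor_names),
        n_presences=n_pres,
        n_absences=int((y == 0).sum()),
        seed=seed,
        feature_spec=spec,
        coef=coef,
        intercept=intercept,
        cloglog_offset=c,
        penalty_C=float(best_C),
    )


def fit_forest(
    train: pd.DataFrame,
    predictor_names: list[str] | None = None,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> FittedSDM:
    """Fit the random-forest member (500 trees, mtry = floor(sqrt(p)))."""
    if predictor_names is None:
        predictor_names = [c for c in train.columns if c not in ("label", "cell")]
    X, y = _split_table(train, predictor_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    p = X.shape[1]
    if mtry is None:
        mtry = default_mtry(p)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    ).fit(X, y)
    return FittedSDM(
        algorithm="forest",
        predictor_names=tuple(predictor_names),
        n_presences=int((y == 1).sum()),
        n_absences=int((y == 0).sum()),
        seed=seed,
        forest=forest,
    )


def default_mtry(p: int) -> int:
    """Candidate predictors per split: floor(sqrt(p)) (2 for the 7-layer stack)."""
    return max(1, math.floor(math.sqrt(p)))


def predict_surface(
    model: FittedSDM, stack: PredictorStack, block_rows: int = 64
) -> Raster:
    """Project a fitted model across a predictor stack.

    Evaluates valid cells in horizontal blocks of ``block_rows`` grid rows so
    memory stays bounded on large grids; masked cells stay masked.  Layer
    order in the stack is irrelevant — columns are pulled by predictor name.
    """
    missing = set(model.predictor_names) - set(stack.names)
    if missing:
        raise KeyError(f"stack is missing model predictors: {sorted(missing)}")
    grid = stack.grid
    out = np.full(grid.shape, np.nan)
    valid = stack.valid_mask
    layer_arrays = {n: stack.layers[n] for n in model.predictor_names}
    for r0 in range(0, grid.n_rows, block_rows):
        r1 = min(r0 + block_rows, grid.n_rows)
        vblock = valid[r0:r1]
        rr, cc = np.nonzero(vblock)
        if rr.size == 0:
            continue
        X = np.column_stack(
            [layer_arrays[n].values[r0:r1][rr, cc] for n in model.predictor_names]
        )
        out[r0 + rr, cc] = model.predict(X)
    return Raster(grid, out, ~valid)
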