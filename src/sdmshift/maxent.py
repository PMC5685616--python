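"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs distribution q(cell) = exp(lambda . f(cell)) / Z
over a background sample of landscape cells, fitted by maximizing the
L1-penalized log-likelihood of the presence sample:

    (1/m) * sum_presence lambda . f  -  ln Z  -  sum_j beta_j |lambda_j|

with per-feature penalty beta_j = beta0 * s_j / sqrt(m), where s_j is the
presence-sample standard deviation of feature j (floored at 1e-6) and m the
number of presences. The objective is concave; it is maximized by L-BFGS-B
on the standard positive/negative split lambda = u - v, u, v >= 0, which
handles the L1 term exactly.

Features are the classic linear / quadratic / pairwise-product / threshold
classes on continuous predictors plus one indicator per habitat category.
Feature columns are min-max scaled to [0, 1] using their background ranges;
projection onto new climates clamps each continuous predictor to its
training range by default.

The logistic output p = q e^H / (1 + q e^H), with H the entropy of the
fitted distribution over the background, maps raw probabilities to an
interpretable (0, 1) suitability with typical-presence value 0.5.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ConfigError
from .grid import PredictorStack, RasterGrid


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    """One basis function of the model.

    kind: "linear" | "quadratic" | "product" | "threshold" | "category".
    idx (and idx2 for products) index predictors in the stack; threshold
    features are 1 when predictor idx exceeds `knot` (raw units); category
    features are 1 when the categorical predictor equals `category`.
    """

    kind: str
    idx: int
    idx2: int | None = None
    knot: float | None = None
    category: float | None = None

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return f"L{self.idx}"
        if self.kind == "quadratic":
            return f"Q{self.idx}"
        if self.kind == "product":
            return f"P{self.idx}x{self.idx2}"
        if self.kind == "threshold":
            return f"T{self.idx}@{self.knot:.6g}"
        return f"C{self.idx}={self.category:g}"


def build_features(
    stack: PredictorStack,
    classes: str = "LQPT",
    n_knots: int = 10,
    background_values: np.ndarray | None = None,
) -> list[FeatureDef]:
    """Expand the stack into feature definitions.

    Threshold knots sit at n_knots equally spaced quantiles (levels
    k/(n_knots+1)) of the background values of each continuous predictor;
    by default the whole land surface serves as the knot-placement sample.
    Quadratic implies linear is NOT assumed here: each letter in `classes`
    independently switches its class on.
    """
    if stack.n_layers == 0:
        raise ConfigError("empty predictor stack")
    if n_knots < 2:
        raise ConfigError("n_knots must be >= 2")
    classes = classes.upper()
    for ch in classes:
        if ch not in "LQPT":
            raise ConfigError(f"unknown feature class {ch!r}")
    cont = stack.continuous_indices()
    cat = stack.categorical_indices()
    if background_values is None:
        background_values = stack.values_at(stack.land_cells())
    feats: list[FeatureDef] = []
    if "L" in classes:
        feats += [FeatureDef("linear", i) for i in cont]
    if "Q" in classes:
        feats += [FeatureDef("quadratic", i) for i in cont]
    if "P" in classes:
        feats += [FeatureDef("product", i, idx2=j)
                  for i, j in itertools.combinations(cont, 2)]
    if "T" in classes:
        levels = np.arange(1, n_knots + 1) / (n_knots + 1)
        for i in cont:
            knots = np.quantile(background_values[:, i], levels)
            feats += [FeatureDef("threshold", i, knot=float(k)) for k in knots]
    for i in cat:
        for code in np.unique(background_values[:, i]):
            feats.append(FeatureDef("category", i, category=float(code)))
    return feats


def evaluate_features(features: list[FeatureDef], X: np.ndarray) -> np.ndarray:
    """Feature matrix (n_cells x n_features) from raw predictor values."""
    cols = np.empty((X.shape[0], len(features)))
    for j, f in enumerate(features):
        if f.kind == "linear":
            cols[:, j] = X[:, f.idx]
        elif f.kind == "quadratic":
            cols[:, j] = X[:, f.idx] ** 2
        elif f.kind == "product":
            cols[:, j] = X[:, f.idx] * X[:, f.idx2]
        elif f.kind == "threshold":
            cols[:, j] = (X[:, f.idx] > f.knot).astype(float)
        elif f.kind == "category":
            cols[:, j] = (X[:, f.idx] == f.category).astype(float)
        else:  # pragma: no cover
            raise ConfigError(f"unknown feature kind {f.kind!r}")
    return cols


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    """Fitted feature weights plus everything needed to predict anywhere."""

    features: list[FeatureDef]
    lam: np.ndarray
    log_Z: float
    entropy_H: float
    beta0: float
    #: per-predictor (min, max) over the training background, for clamping
    training_ranges: dict[int, tuple[float, float]]
    #: per-feature (min, max) over the training background, for scaling
    feature_mins: np.ndarray = field(repr=False, default=None)
    feature_maxs: np.ndarray = field(repr=False, default=None)
    n_presences_m: int = 0
    converged: bool = True
    n_iter: int = 0
    objective_history: list[float] = field(default_factory=list, repr=False)

    def scaled_features(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Evaluate and min-max scale features at raw predictor values."""
        if clamp:
            X = X.copy()
            for idx, (lo, hi) in self.training_ranges.items():
                X[:, idx] = np.clip(X[:, idx], lo, hi)
        G = evaluate_features(self.features, X)
        span = self.feature_maxs - self.feature_mins
        safe = np.where(span > 0, span, 1.0)
        G = (G - self.feature_mins) / safe
        G[:, span <= 0] = 0.0
        return G

    def raw_at(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        G = self.scaled_features(X, clamp=clamp)
        return np.exp(G @ self.lam - self.log_Z)

    def logistic_at(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        q = self.raw_at(X, clamp=clamp)
        qe = q * np.exp(self.entropy_H)
        return qe / (1.0 + qe)


def sample_background(
    stack: PredictorStack, n: int = 10000, seed: int = 0
) -> list[tuple[int, int]]:
    """Uniform background sample without replacement from the land mask
    (all land cells when fewer than n). Presences are not excluded."""
    cells = stack.land_cells()
    if n >= len(cells):
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False)
    return [cells[i] for i in idx]


def fit_maxent(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    features: list[FeatureDef],
    beta0: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    Parameters are raw predictor value matrices for the presence sample
    (m x n_pred) and the background sample (N x n_pred), plus the feature
    definitions. Convergence is declared when the objective changes by
    less than `tol` (or after `max_iter` iterations; the status is
    recorded on the model either way).
    """
    m = X_presence.shape[0]
    if m < 1:
        raise ConfigError("need at least one presence")
    G_bg_raw = evaluate_features(features, X_background)
    fmin = G_bg_raw.min(axis=0)
    fmax = G_bg_raw.max(axis=0)
    span = fmax - fmin
    active = span > 0

    ranges = {
        idx: (float(X_background[:, idx].min()), float(X_background[:, idx].max()))
        for idx in sorted({f.idx for f in features}
                          | {f.idx2 for f in features if f.idx2 is not None})
    }
    model = MaxentModel(
        features=list(features),
        lam=np.zeros(len(features)),
        log_Z=float(np.log(X_background.shape[0])),
        entropy_H=float(np.log(X_background.shape[0])),
        beta0=beta0,
        training_ranges=ranges,
        feature_mins=fmin,
        feature_maxs=fmax,
        n_presences_m=m,
    )
    if not active.any():
        warnings.warn("all features constant over the background; uniform model")
        return model

    G_bg = model.scaled_features(X_background)[:, active]
    G_pr = model.scaled_features(X_presence)[:, active]
    a = G_pr.mean(axis=0)
    s = np.maximum(G_pr.std(axis=0), 1e-6)
    beta = beta0 * s / np.sqrt(m)
    J = active.sum()

    def smooth(lam):
        z = G_bg @ lam
        lse = logsumexp(z)
        p = np.exp(z - lse)
        val = -(a @ lam) + lse
        grad = -a + p @ G_bg
        return val, grad

    def objective(w):
        u, v = w[:J], w[J:]
        lam = u - v
        val, grad = smooth(lam)
        val += beta @ (u + v)
        return val, np.concatenate([grad + beta, -grad + beta])

    history: list[float] = []

    def cb(w):
        history.append(float(objective(w)[0]))

    x0 = np.zeros(2 * J)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * J),
        callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    lam_active = res.x[:J] - res.x[J:]
    # shrink numerically-zero weights to exact zero
    lam_active[np.abs(lam_active) < 1e-10] = 0.0
    lam = np.zeros(len(features))
    lam[active] = lam_active

    z = G_bg @ lam_active
    log_Z = float(logsumexp(z))
    logq = z - log_Z
    q = np.exp(logq)
    entropy = float(-(q * logq).sum())

    model.lam = lam
    model.log_Z = log_Z
    model.entropy_H = entropy
    model.converged = bool(res.success) or res.nit >= max_iter
    model.n_iter = int(res.nit)
    model.objective_history = history
    return model


def fit_on_cells(
    stack: PredictorStack,
    presence_cells,
    background_cells,
    features: list[FeatureDef],
    **kwargs,
) -> MaxentModel:
    """Convenience wrapper fitting on cell index sets of a stack."""
    Xp = stack.values_at(sorted(presence_cells))
    Xb = stack.values_at(list(background_cells))
    return fit_maxent(Xp, Xb, features, **kwargs)


# ---------------------------------------------------------------------------
# Prediction on grids
# ---------------------------------------------------------------------------

def _predict_grid(model: MaxentModel, stack: PredictorStack, fn) -> RasterGrid:
    needed = {f.idx for f in model.features} | {
        f.idx2 for f in model.features if f.idx2 is not None
    }
    if needed and max(needed) >= stack.n_layers:
        raise ConfigError("stack is missing predictors required by the model")
    land = stack.land_mask
    cells = np.nonzero(land)
    X = np.column_stack([lyr.values[cells] for lyr in stack.layers])
    out = np.zeros(stack.grid.shape)
    out[cells] = fn(X)
    return stack.grid.like(out, mask=~land)


def predict_raw(model: MaxentModel, stack: PredictorStack, clamp: bool = False) -> RasterGrid:
    """Raw Gibbs output q = exp(lambda . f) / Z per land cell (Z from the
    training background, so values over that background sum to one)."""
    return _predict_grid(model, stack, lambda X: model.raw_at(X, clamp=clamp))


def predict_logistic(model: MaxentModel, stack: PredictorStack, clamp: bool = True) -> RasterGrid:
    """Logistic suitability in (0,1); continuous predictors are clamped to
    their training ranges before feature evaluation unless clamp=False."""
    return _predict_grid(model, stack, lambda X: model.logistic_at(X, clamp=clamp))


# ---------------------------------------------------------------------------
# JSON round-trip for model files
# ---------------------------------------------------------------------------

def model_to_dict(model: MaxentModel) -> dict:
    return {
        "features": [
            {"kind": f.kind, "idx": f.idx, "idx2": f.idx2, "knot": f.knot,
             "category": f.category}
            for f in model.features
        ],
        "lambda": model.lam.tolist(),
        "log_Z": model.log_Z,
        "entropy_H": model.entropy_H,
        "beta0": model.beta0,
        "training_ranges": {str(k): list(v) for k, v in model.training_ranges.items()},
        "feature_mins": model.feature_mins.tolist(),
        "feature_maxs": model.feature_maxs.tolist(),
        "n_presences_m": model.n_presences_m,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }


def model_from_dict(doc: dict) -> MaxentModel:
    feats = [
        FeatureDef(d["kind"], d["idx"], idx2=d["idx2"], knot=d["knot"],
                   category=d["category"])
        for d in doc["features"]
    ]
    return MaxentModel(
        features=feats,
        lam=np.asarray(doc["lambda"], dtype=float),
        log_Z=float(doc["log_Z"]),
        entropy_H=float(doc["entropy_H"]),
        beta0=float(doc["beta0"]),
        training_ranges={int(k): tuple(v) for k, v in doc["training_ranges"].items()},
        feature_mins=np.asarray(doc["feature_mins"], dtype=float),
        feature_maxs=np.asarray(doc["feature_maxs"], dtype=float),
        n_presences_m=int(doc["n_presences_m"]),
        converged=bool(doc["converged"]),
        n_iter=int(doc["n_iter"]),
    )
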