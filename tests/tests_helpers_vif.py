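"""Shared helpers for the VIF checks: matrix-to-stack conversion, the
independent least-squares oracle, and the 23-predictor construction."""

import numpy as np

from sdmshift.grid import PredictorStack, RasterGrid


def matrix_to_stack(X: np.ndarray) -> PredictorStack:
    layers = [
        RasterGrid(X[:, j][None, :], np.zeros((1, X.shape[0]), bool), 0.0, 1.0,
                   1.0, "planar")
        for j in range(X.shape[1])
    ]
    return PredictorStack(layers=layers,
                          names=[f"x{j}" for j in range(X.shape[1])],
                          kinds=["continuous"] * X.shape[1])


def oracle_vif(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
    return 1.0 / (1.0 - r2)


def build_23_predictor_stack(seed: int = 0) -> PredictorStack:
    """Eleven independent base predictors plus twelve noisy linear
    combinations of them, shuffled: rank-11 structure in 23 columns."""
    rng = np.random.default_rng(seed)
    n = 2000
    bases = rng.normal(size=(n, 11))
    combos = np.column_stack(
        [bases @ rng.normal(size=11) + rng.normal(scale=0.01, size=n)
         for _ in range(12)]
    )
    X = np.column_stack([bases, combos])
    return matrix_to_stack(X[:, rng.permutation(23)])
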