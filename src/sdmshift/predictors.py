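"""Predictor preparation: vegetation-index summaries and collinearity
screening by iterated variance inflation factors.

The VIF of predictor j is 1/(1 - R^2_j) where R^2_j comes from an ordinary
least-squares regression of predictor j on every other *continuous*
predictor. Screening drops the single worst predictor per round, recomputes,
and stops once every remaining score is below the threshold (default 10).
Categorical layers are excluded from the regressions and always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, SamplingError
from .grid import PredictorStack, RasterGrid

#: reported VIF when a predictor is a perfect linear combination of the rest
VIF_CAP = 1e12


def derive_ndvi_layers(composites: list[RasterGrid]) -> tuple[RasterGrid, RasterGrid]:
    """Per-cell maximum and (max - min) over a composite time series.

    The maximum indicates how much vegetation a cell ever carries; the
    difference measures its seasonal variability. A cell masked in any
    composite is masked in both outputs.
    """
    if len(composites) < 2:
        raise AlignmentError("need >= 2 composites")
    first = composites[0]
    for comp in composites[1:]:
        first.assert_aligned(comp)
    stack = np.stack([c.values for c in composites])
    masks = np.stack([c.mask for c in composites])
    any_masked = masks.any(axis=0)
    vmax = stack.max(axis=0)
    vmin = stack.min(axis=0)
    max_layer = first.like(np.where(any_masked, 0.0, vmax), mask=any_masked)
    diff_layer = first.like(np.where(any_masked, 0.0, vmax - vmin), mask=any_masked)
    return max_layer, diff_layer


@dataclass
class VIFReport:
    """Audit trail of the elimination loop.

    rounds[i] holds the scores computed in round i and the name removed at
    the end of that round (None in the final round).
    """

    rounds: list[tuple[dict[str, float], str | None]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


def sample_cells_for_vif(
    stack: PredictorStack, n: int = 5000, seed: int = 0
) -> list[tuple[int, int]]:
    """Random land-cell sample used for the VIF regressions."""
    cells = stack.land_cells()
    if n >= len(cells):
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False)
    return [cells[i] for i in idx]


def vif_scores(
    stack: PredictorStack, sample_cells: list[tuple[int, int]]
) -> dict[str, float]:
    """VIF per continuous predictor over the sampled cells.

    Perfect collinearity is reported as the cap (1e12) rather than raising.
    """
    cont = stack.continuous_indices()
    if len(cont) < 2:
        raise SamplingError("need >= 2 continuous predictors")
    if len(sample_cells) <= len(cont) + 1:
        raise SamplingError("sample size must exceed number of predictors + 1")
    X = stack.values_at(sample_cells)[:, cont]
    names = [stack.names[i] for i in cont]
    return dict(zip(names, _vif_from_matrix(X)))


def _vif_from_matrix(X: np.ndarray) -> list[float]:
    n, p = X.shape
    out = []
    for j in range(p):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = ((y - y.mean()) ** 2).sum()
        if sst <= 0:
            out.append(VIF_CAP)
            continue
        r2 = 1.0 - (resid ** 2).sum() / sst
        if 1.0 - r2 < 1.0 / VIF_CAP:
            out.append(VIF_CAP)
        else:
            out.append(1.0 / (1.0 - r2))
    return out


def vif_select(
    stack: PredictorStack,
    threshold: float = 10.0,
    sample_cells: list[tuple[int, int]] | None = None,
    n_sample: int = 5000,
    seed: int = 0,
) -> VIFReport:
    """Greedy elimination: drop the highest-VIF predictor, recompute, stop
    when all scores are below the threshold.

    Ties in the maximum are broken by stack order (earliest wins).
    Categorical predictors never enter the regressions and are always
    retained. With fewer than two continuous predictors left the loop
    terminates and everything is retained.
    """
    if sample_cells is None:
        sample_cells = sample_cells_for_vif(stack, n=n_sample, seed=seed)
    report = VIFReport()
    current = stack
    while True:
        cont = current.continuous_indices()
        if len(cont) < 2:
            report.rounds.append(({}, None))
            break
        scores = vif_scores(current, sample_cells)
        worst = max(scores.values())
        if worst < threshold:
            report.rounds.append((scores, None))
            break
        # earliest-in-stack-order among the maxima
        removed = next(
            current.names[i] for i in cont if scores[current.names[i]] == worst
        )
        report.rounds.append((scores, removed))
        keep = [n for n in current.names if n != removed]
        current = current.subset(keep)
    report.retained = list(current.names)
    return report


def vif_report_frame(report: VIFReport):
    """Long-format DataFrame (round, predictor, vif, removed_flag)."""
    import pandas as pd

    rows = []
    for rnd, (scores, removed) in enumerate(report.rounds):
        for name, score in scores.items():
            rows.append(
                {"round": rnd, "predictor": name, "vif": score,
                 "removed_flag": name == removed}
            )
    return pd.DataFrame(rows, columns=["round", "predictor", "vif", "removed_flag"])
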