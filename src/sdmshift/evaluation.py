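"""Cross-validation replicates, AUC / TSS scoring, the 10% training
presence threshold, and the species inclusion filters.

Evaluation is presence-background: the shared background sample stands in
for absences both in the rank AUC (so a perfect 1.0 is not attainable in
theory, since background cells include suitable habitat) and in the
specificity term of the TSS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import EvaluationError
from .grid import PredictorStack
from .maxent import FeatureDef, MaxentModel, fit_maxent


# ---------------------------------------------------------------------------
# Elementary scores
# ---------------------------------------------------------------------------

def auc(pos_scores, neg_scores) -> float:
    """Rank-based (Mann-Whitney) AUC: P(pos > neg) + 0.5 P(pos = neg)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("AUC needs non-empty score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def tss(pred_binary, truth) -> float:
    """True skill statistic = sensitivity + specificity - 1.

    Returns NaN (flagged missing) when the truth vector has no positives
    or no negatives.
    """
    pred = np.asarray(pred_binary).astype(bool)
    tru = np.asarray(truth).astype(bool)
    n_pos = tru.sum()
    n_neg = (~tru).sum()
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    sens = (pred & tru).sum() / n_pos
    spec = (~pred & ~tru).sum() / n_neg
    return float(sens + spec - 1.0)


def threshold_10tp(train_presence_scores, percent: float = 10.0) -> float:
    """Nearest-rank lower-percentile training-presence threshold.

    The largest observed score t such that at least (100 - percent)% of the
    training presence scores are >= t; classification uses score >= t.
    percent=0 reduces to the minimal-training-presence rule.
    """
    scores = np.sort(np.asarray(train_presence_scores, dtype=float))
    if scores.size == 0:
        raise EvaluationError("empty training score list")
    k = math.floor(scores.size * percent / 100.0)
    k = min(k, scores.size - 1)
    return float(scores[k])


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def split_folds(cells, k: int = 10, seed: int = 0) -> list[list]:
    """Random partition into k folds with sizes differing by at most one.

    Replicate i trains on all folds except fold i. When there are fewer
    cells than folds, k is reduced to the number of cells with a warning.
    """
    cells = sorted(cells)
    if len(cells) < k:
        warnings.warn(f"only {len(cells)} cells; reducing k from {k}")
        k = len(cells)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(cells[idx])
    return folds


@dataclass
class ReplicateResult:
    """One cross-validation replicate: model, threshold, and test scores."""

    replicate_index: int
    model: MaxentModel
    threshold: float
    train_cells: list
    test_cells: list
    auc_test: float
    tss_test: float


@dataclass
class SpeciesEvaluation:
    species_id: str
    n_cells: int
    replicates: list[ReplicateResult] = field(default_factory=list)
    mean_auc: float = float("nan")
    sd_auc: float = float("nan")
    mean_tss: float = float("nan")
    included: bool = True
    exclusion_reason: str | None = None


def evaluate_species(
    species_id: str,
    presence_cells,
    background_cells,
    stack: PredictorStack,
    features: list[FeatureDef],
    k: int = 10,
    beta0: float = 1.0,
    max_iter: int = 1000,
    threshold_percent: float = 10.0,
    seed: int = 0,
) -> SpeciesEvaluation:
    """Run k-fold cross-validation for one species.

    Each replicate fits on the training presences against the shared
    background, takes its own 10% training-presence threshold, and scores
    the held-out presences against the background (AUC, and TSS at the
    replicate threshold).
    """
    presence_cells = sorted(presence_cells)
    background_cells = list(background_cells)
    folds = split_folds(presence_cells, k=k, seed=seed)
    Xb = stack.values_at(background_cells)
    Xall = stack.values_at(presence_cells)
    index_of = {c: i for i, c in enumerate(presence_cells)}

    replicates: list[ReplicateResult] = []
    for i, test in enumerate(folds):
        train = [c for j, f in enumerate(folds) if j != i for c in f]
        Xtr = Xall[[index_of[c] for c in train]]
        Xte = Xall[[index_of[c] for c in test]]
        model = fit_maxent(Xtr, Xb, features, beta0=beta0, max_iter=max_iter)
        train_scores = model.logistic_at(Xtr, clamp=False)
        thr = threshold_10tp(train_scores, percent=threshold_percent)
        test_scores = model.logistic_at(Xte, clamp=False)
        bg_scores = model.logistic_at(Xb, clamp=False)
        a = auc(test_scores, bg_scores)
        pred = np.concatenate([test_scores, bg_scores]) >= thr
        truth = np.concatenate(
            [np.ones(len(test_scores), bool), np.zeros(len(bg_scores), bool)]
        )
        replicates.append(
            ReplicateResult(
                replicate_index=i,
                model=model,
                threshold=thr,
                train_cells=train,
                test_cells=list(test),
                auc_test=a,
                tss_test=tss(pred, truth),
            )
        )
    aucs = np.array([r.auc_test for r in replicates])
    tsss = np.array([r.tss_test for r in replicates])
    return SpeciesEvaluation(
        species_id=species_id,
        n_cells=len(presence_cells),
        replicates=replicates,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        mean_tss=float(np.nanmean(tsss)) if not np.all(np.isnan(tsss)) else float("nan"),
    )


def filter_species(
    evaluations: list[SpeciesEvaluation],
    min_records: int = 10,
    auc_floor: float = 0.7,
) -> tuple[list[SpeciesEvaluation], list[tuple[str, str]]]:
    """Apply the inclusion filters and annotate exclusions.

    Species with fewer than `min_records` occupied cells are dropped as
    "too_few_records"; species whose mean cross-validated AUC falls below
    `auc_floor` are dropped as "low_auc". Boundary values are inclusive
    (exactly min_records cells or exactly the floor AUC stay in).
    """
    included: list[SpeciesEvaluation] = []
    log: list[tuple[str, str]] = []
    for ev in evaluations:
        if ev.n_cells < min_records:
            ev.included = False
            ev.exclusion_reason = "too_few_records"
        elif not ev.mean_auc >= auc_floor:
            ev.included = False
            ev.exclusion_reason = "low_auc"
        else:
            ev.included = True
            ev.exclusion_reason = None
            included.append(ev)
        if not ev.included:
            log.append((ev.species_id, ev.exclusion_reason))
    return included, log
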