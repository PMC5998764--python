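"""Enzyme-wise cross-validation, ranking metrics and threshold tuning.

Splitting is done *by enzyme*, not by substrate: substrates of one enzyme
are physico-chemically similar, so a substrate-level split would leak
near-duplicates of test molecules into training and overstate performance.
With enzymes partitioned into k folds, the substrates catalyzed only by a
fold's enzymes are held out entirely — normalization, feature ranking and
the pair model are fitted without ever seeing them, and positive pair
labels in training are defined only by the enzymes outside the fold.

Evaluation is at the (query, enzyme) level: each held-out enzyme is scored
for each of its fold's substrates against its own remaining substrates
(leave-query-out), the individual scores are integrated, and the pooled
integrated scores across folds give the AUC and, at a chosen threshold,
the confusion metrics (sensitivity, specificity, MCC, PPV).  The Matthews
correlation coefficient drives threshold selection because the instance
set is overwhelmingly negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import (
    DegenerateLabelsError,
    DomainError,
    EmptyInputError,
    EvaluationError,
)
from .integration import INTEGRATORS, decide
from .io_model import DescriptorMatrix, ReactionSet
from .pair_features import apply_normalization
from .pairwise_model import score_query_vs_enzyme
from .predictor import EnzymeReactionPredictor

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "ThresholdCurve",
    "auc",
    "confusion_metrics",
    "threshold_scan",
    "partition_enzymes",
    "pooled_cv_instances",
    "cross_validate",
    "default_threshold_grid",
]


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Confusion metrics (and optionally AUC) at one decision threshold.

    Metrics with a zero denominator are reported as 0 and named in
    ``flags``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sen: float
    spe: float
    mcc: float
    ppv: float
    threshold: float
    auc: float | None = None
    pair_auc: float | None = None
    flags: list[str] = field(default_factory=list)
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sen": self.sen, "spe": self.spe, "mcc": self.mcc, "ppv": self.ppv,
            "threshold": self.threshold, "auc": self.auc, "pair_auc": self.pair_auc,
            "flags": list(self.flags), "per_fold": list(self.per_fold),
        }
        return d


def confusion_metrics(scores, labels, threshold: float) -> MetricsReport:
    """Sensitivity, specificity, MCC and PPV at a fixed threshold.

    Decisions use the inclusive rule (score >= threshold -> positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise EmptyInputError("no instances to score")
    pred = np.array([decide(s, threshold) for s in scores])
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    flags: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sen = _ratio(tp, tp + fn, "sen")
    spe = _ratio(tn, tn + fp, "spe")
    ppv = _ratio(tp, tp + fp, "ppv")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sen=float(sen), spe=float(spe), mcc=float(mcc), ppv=float(ppv),
        threshold=float(threshold), flags=flags,
    )


def default_threshold_grid(step: float = 0.05) -> np.ndarray:
    """Inclusive threshold grid over [0, 1]."""
    n = round(1.0 / step)
    return np.linspace(0.0, 1.0, n + 1)


@dataclass(frozen=True)
class ThresholdCurve:
    """MCC as a function of decision threshold, and the best threshold."""

    thresholds: np.ndarray
    mcc: np.ndarray
    best_threshold: float

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.mcc):
            raise DomainError("grid and curve lengths differ")


def threshold_scan(scores, labels, grid=None) -> ThresholdCurve:
    """MCC at every grid threshold; best = lowest argmax."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("threshold scan needs both classes")
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise DomainError("threshold grid must be strictly increasing")
    mccs = np.array([confusion_metrics(scores, labels, t).mcc for t in grid])
    best = float(grid[int(np.argmax(mccs))])  # argmax returns the first max
    return ThresholdCurve(thresholds=grid, mcc=mccs, best_threshold=best)


def partition_enzymes(R: ReactionSet, k: int, seed: int) -> dict[str, int]:
    """Assign every enzyme to one of k folds, sizes differing by at most 1.

    Deterministic for a given seed: enzymes are sorted, shuffled with a
    seeded generator, and dealt round-robin.
    """
    enzymes = sorted(R.enzymes)
    if k < 2 or k > len(enzymes):
        raise DomainError(
            f"fold count must satisfy 2 <= k <= {len(enzymes)}, got {k}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(enzymes))
    return {enzymes[j]: i % k for i, j in enumerate(order)}


def _fold_split(
    R: ReactionSet, assignment: dict[str, int], fold: int
) -> tuple[set[str], set[str], ReactionSet]:
    """Test enzymes, held-out substrates, and the leakage-free training
    reaction set for one fold.

    Held-out substrates are those catalyzed *only* by the fold's enzymes;
    training reactions keep only out-of-fold enzymes and non-held-out
    substrates, so training labels never encode in-fold relations.
    """
    test_enzymes = {e for e, f in assignment.items() if f == fold}
    s2e = R.substrate_to_enzymes()
    held_out = {s for s, es in s2e.items() if es <= test_enzymes}
    train_enzymes = set(R.enzymes) - test_enzymes
    train_substrates = set(R.substrates) - held_out
    R_train = R.restrict(enzymes=train_enzymes, substrates=train_substrates)
    return test_enzymes, held_out, R_train


def fit_fold_model(
    D: DescriptorMatrix,
    R: ReactionSet,
    test_enzymes: set[str],
    n_features: int,
    learner: str = "linear",
    seed: int = 0,
) -> EnzymeReactionPredictor:
    """Fit the pipeline for one fold using only out-of-fold information.

    Exposed separately so leakage can be audited: the fitted model is a
    pure function of the out-of-fold substrates and reactions, so deleting
    the held-out substrate rows from ``D`` must not change it.
    """
    s2e = R.substrate_to_enzymes()
    held_out = {s for s, es in s2e.items() if es <= set(test_enzymes)}
    R_train = R.restrict(
        enzymes=set(R.enzymes) - set(test_enzymes),
        substrates=set(R.substrates) - held_out,
    )
    if not R_train.reactions:
        raise EvaluationError("fold leaves no training reactions")
    model = EnzymeReactionPredictor(
        n_features=n_features, learner=learner, random_state=seed
    )
    return model.fit(D, R_train)


def pooled_cv_instances(
    D: DescriptorMatrix,
    R: ReactionSet,
    k: int = 20,
    n_features: int = 500,
    learner: str = "linear",
    method: str = "weighted",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[dict]]:
    """Pooled (query, enzyme) evaluation instances across all folds.

    Returns ``(scores, labels, pair_scores, pair_labels, per_fold)``
    where ``scores``/``labels`` are the integrated score and truth of
    every evaluable instance and the pair-level arrays hold the
    underlying individual (query, substrate) scores as a diagnostic.
    """
    if method not in INTEGRATORS:
        raise DomainError(f"unknown integration method {method!r}")
    integrator = INTEGRATORS[method]
    assignment = partition_enzymes(R, k, seed)
    e2s = R.enzyme_to_substrates()

    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    pair_scores: list[float] = []
    pair_labels: list[int] = []
    per_fold: list[dict] = []
    evaluated = 0

    for fold in range(k):
        test_enzymes, held_out, R_train = _fold_split(R, assignment, fold)
        if not R_train.reactions:
            logger.warning("fold %d: no training reactions, skipped", fold)
            continue
        try:
            model = EnzymeReactionPredictor(
                n_features=n_features, learner=learner, random_state=seed
            ).fit(D, R_train)
        except DegenerateLabelsError:
            logger.warning("fold %d: single-class training pairs, skipped", fold)
            continue

        # queries: every substrate with a reaction to an in-fold enzyme
        queries = sorted({s for e in test_enzymes for s in e2s.get(e, ())})
        fold_scores: list[float] = []
        fold_labels: list[int] = []
        D_norm = apply_normalization(D, model.normalization_).data
        for q in queries:
            if q not in D_norm.index:
                continue
            q_vec = D_norm.loc[q, model.selected_features_].to_numpy(dtype=float)
            for e in sorted(test_enzymes):
                refs = sorted(s for s in e2s.get(e, ()) if s != q and s in D_norm.index)
                if not refs:
                    continue
                rows = D_norm.loc[refs, model.selected_features_]
                s_i = score_query_vs_enzyme(model.pair_model_, q_vec, rows)
                label = int((e, q) in R.reactions)
                fold_scores.append(integrator(s_i))
                fold_labels.append(label)
                pair_scores.extend(s_i)
                pair_labels.extend([label] * len(s_i))
        if not fold_labels or sum(fold_labels) == 0:
            logger.warning("fold %d: no positive evaluation instance, skipped", fold)
            continue
        evaluated += 1
        pooled_scores.extend(fold_scores)
        pooled_labels.extend(fold_labels)
        detail = {
            "fold": fold,
            "n_test_enzymes": len(test_enzymes),
            "n_held_out_substrates": len(held_out),
            "n_instances": len(fold_labels),
            "n_positive": int(sum(fold_labels)),
        }
        if len(set(fold_labels)) == 2:
            detail["auc"] = auc(fold_scores, fold_labels)
        per_fold.append(detail)

    if evaluated == 0:
        raise EvaluationError("all folds skipped: no evaluable instances")
    return (
        np.asarray(pooled_scores),
        np.asarray(pooled_labels),
        np.asarray(pair_scores),
        np.asarray(pair_labels),
        per_fold,
    )


def cross_validate(
    D: DescriptorMatrix,
    R: ReactionSet,
    k: int = 20,
    n_features: int = 500,
    learner: str = "linear",
    method: str = "weighted",
    threshold: float = 0.75,
    seed: int = 0,
) -> MetricsReport:
    """Enzyme-wise k-fold cross-validation of the full pipeline.

    Returns pooled (query, enzyme)-level metrics: AUC over the integrated
    scores of all folds' instances, confusion metrics at ``threshold``,
    per-fold detail in ``per_fold``, and a pooled pair-level AUC over the
    individual (query, substrate) scores as a diagnostic.
    """
    scores, labels, pair_scores, pair_labels, per_fold = pooled_cv_instances(
        D, R, k=k, n_features=n_features, learner=learner, method=method, seed=seed
    )
    report = confusion_metrics(scores, labels, threshold)
    if len(np.unique(labels)) == 2:
        report.auc = auc(scores, labels)
    if len(np.unique(pair_labels)) == 2:
        report.pair_auc = auc(pair_scores, pair_labels)
    report.per_fold = per_fold
    return report
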