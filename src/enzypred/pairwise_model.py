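"""Train and apply the pairwise same-enzyme scorer.

The canonical learner is multiple linear regression of the 0/1 same-enzyme
label on the selected difference features; the continuous fitted value is
the pair score (higher = more likely same enzyme).  The full pair set is
used as-is — no class rebalancing, weighting or subsampling — so the model
sees the natural ~0.7% positive rate.  Alternative learners (naive Bayes,
random forest, a small neural network) plug in behind the same contract
and score with their positive-class probability.

Raw pair scores are clipped to [0, 1] before integration so that the
integrated score stays comparable with the 0.75 decision threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateLabelsError, EmptyInputError, SchemaError
from .pair_features import NormalizationParams, PairFeatureSet, pair_feature

logger = logging.getLogger(__name__)

__all__ = [
    "PairModel",
    "fit_pair_model",
    "score_pair",
    "score_query_vs_enzyme",
    "LEARNERS",
]

LEARNERS = ("linear", "naive_bayes", "random_forest", "neural_network")


@dataclass
class PairModel:
    """A fitted pairwise same-enzyme scorer.

    For the linear learner, ``coef``/``intercept`` hold the ordinary
    least-squares solution over ``feature_names``; other learners keep
    their fitted scikit-learn estimator in ``estimator``.  The
    normalization parameters the model expects its inputs to carry travel
    with the model so query molecules can be mapped into the same space.
    """

    learner: str
    feature_names: list[str]
    coef: np.ndarray | None = None
    intercept: float = 0.0
    normalization: NormalizationParams | None = None
    estimator: Any = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.learner == "linear" and self.coef is not None:
            if len(self.coef) != len(self.feature_names):
                raise SchemaError(
                    f"{len(self.coef)} coefficients for "
                    f"{len(self.feature_names)} features"
                )

    def to_json(self) -> str:
        """Serialize a linear model as a self-describing JSON document."""
        if self.learner != "linear":
            raise NotImplementedError(
                "only the linear learner has a JSON serialization"
            )
        doc = {
            "format": "enzypred-pair-model",
            "version": 1,
            "learner": self.learner,
            "feature_names": self.feature_names,
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "normalization": None
            if self.normalization is None
            else self.normalization.to_dict(),
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PairModel":
        doc = json.loads(text)
        if doc.get("format") != "enzypred-pair-model":
            raise SchemaError("not an enzypred pair-model document")
        return cls(
            learner=doc["learner"],
            feature_names=list(doc["feature_names"]),
            coef=np.asarray(doc["coef"], dtype=float),
            intercept=float(doc["intercept"]),
            normalization=None
            if doc.get("normalization") is None
            else NormalizationParams.from_dict(doc["normalization"]),
            metadata=dict(doc.get("metadata", {})),
        )


def _make_estimator(learner: str, seed: int):
    if learner == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    if learner == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if learner == "neural_network":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=500, random_state=seed
        )
    raise SchemaError(f"unknown learner {learner!r}; choose from {LEARNERS}")


def fit_pair_model(
    P: PairFeatureSet,
    features: Sequence[str],
    learner: str = "linear",
    seed: int = 0,
    normalization: NormalizationParams | None = None,
) -> PairModel:
    """Fit the pairwise scorer on the selected feature columns.

    The linear learner solves ordinary least squares of the 0/1 label on
    the columns via a minimum-norm solver, so rank-deficient designs fit
    with a warning rather than failing; the fit is deterministic and the
    seed is ignored.  Stochastic learners consume the seed.
    """
    features = list(features)
    missing = [f for f in features if f not in P.feature_names]
    if missing:
        raise SchemaError(f"features absent from the pair dataset: {missing}")
    y = P.labels.astype(float)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("pair labels contain a single class")
    col_idx = [P.feature_names.index(f) for f in features]
    X = P.features[:, col_idx].astype(float)
    meta = {
        "n_pairs": int(len(y)),
        "n_positive": int(y.sum()),
        "seed": int(seed),
    }

    if learner == "linear":
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            logger.warning(
                "rank-deficient design (rank %d < %d); using the "
                "minimum-norm least-squares solution",
                rank, design.shape[1],
            )
        return PairModel(
            learner="linear",
            feature_names=features,
            coef=beta[1:],
            intercept=float(beta[0]),
            normalization=normalization,
            metadata=meta,
        )

    est = _make_estimator(learner, seed)
    est.fit(X, y.astype(int))
    return PairModel(
        learner=learner,
        feature_names=features,
        estimator=est,
        normalization=normalization,
        metadata=meta,
    )


def score_pair(M: PairModel, f) -> float:
    """Raw pair score for one difference-feature vector.

    For the linear learner this is the linear predictor and may fall
    outside [0, 1]; clipping happens at integration time.
    """
    return float(score_pairs(M, np.asarray(f, dtype=float)[None, :])[0])


def score_pairs(M: PairModel, F: np.ndarray) -> np.ndarray:
    """Vectorized :func:`score_pair` over the rows of ``F``."""
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] != len(M.feature_names):
        raise SchemaError(
            f"feature block of shape {F.shape} does not align with "
            f"{len(M.feature_names)} model features"
        )
    if M.learner == "linear":
        return M.intercept + F @ M.coef
    return M.estimator.predict_proba(F)[:, 1]


def score_query_vs_enzyme(
    M: PairModel,
    q_row,
    substrate_rows,
) -> list[float]:
    """Individual scores between a query and each known substrate.

    ``q_row`` and every substrate row must already be normalized with the
    model's parameters and aligned to its feature list.  Scores come back
    order-aligned with the input substrates, clipped to [0, 1] ready for
    integration.
    """
    if isinstance(substrate_rows, pd.DataFrame):
        rows = substrate_rows.to_numpy(dtype=float)
    else:
        rows = np.asarray(substrate_rows, dtype=float)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[0] == 0:
        raise EmptyInputError("enzyme has no substrate rows to score against")
    q = np.asarray(q_row, dtype=float)
    if q.shape != (rows.shape[1],):
        raise SchemaError(
            f"query vector of length {q.size} vs substrate rows of width {rows.shape[1]}"
        )
    feats = np.abs(rows - q)  # == pair_feature(q, row) per row
    raw = score_pairs(M, feats)
    return [float(v) for v in np.clip(raw, 0.0, 1.0)]
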