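"""End-to-end estimator: from a reaction table and descriptor matrix to
ranked per-enzyme predictions for query molecules.

:class:`EnzymeReactionPredictor` is the scikit-learn-style front door of
the package.  ``fit`` runs the full training pipeline — z-score the
substrate descriptors, build the exhaustive labeled pair dataset, rank
difference features by point-biserial correlation, keep the top n, and
fit the pairwise scorer — and ``predict``/``predict_one`` score query
molecules against every enzyme with the chosen integrator and threshold.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .errors import CoverageError
from .feature_rank import (
    DEFAULT_CORRELATION_FLOOR,
    RankedFeatures,
    rank_features,
    select_top,
)
from .integration import DEFAULT_THRESHOLD, EnzymePrediction, predict_enzymes
from .io_model import DescriptorMatrix, ReactionSet
from .pair_features import (
    apply_normalization,
    build_pair_dataset,
    fit_normalization,
)
from .pairwise_model import PairModel, fit_pair_model

__all__ = ["EnzymeReactionPredictor"]


class EnzymeReactionPredictor(BaseEstimator):
    """Predict which enzymes can catalyze a query molecule.

    Parameters
    ----------
    n_features : int, default 500
        Number of top-ranked difference features used by the pair model
        (capped at the number of usable descriptor columns).
    learner : {"linear", "naive_bayes", "random_forest", "neural_network"}
        Pairwise scorer; multiple linear regression is the canonical one.
    method : {"weighted", "mean", "max", "noisy_or"}, default "weighted"
        Score-integration method.
    threshold : float, default 0.75
        Decision threshold on the integrated score (inclusive).
    correlation_floor : float, default 0.01
        |r_pb| below which a feature is excluded from ranking outright.
    random_state : int, default 0
        Seed for stochastic learners; the linear learner ignores it.

    Attributes
    ----------
    normalization_ : NormalizationParams
        Column z-scoring parameters fitted on the training substrates.
    ranking_ : RankedFeatures
        Difference features ordered by |point-biserial correlation|.
    selected_features_ : list of str
        The features the pair model uses.
    pair_model_ : PairModel
        The fitted pairwise same-enzyme scorer.
    reactions_ : ReactionSet
        The training reactions (reference substrates at prediction time).
    substrate_matrix_ : DescriptorMatrix
        Normalized descriptor rows of the training substrates.

    Examples
    --------
    >>> from enzypred.synthetic import simulate_dataset, SimulationParams
    >>> D, R, _ = simulate_dataset(SimulationParams(seed=7))
    >>> model = EnzymeReactionPredictor(n_features=30).fit(D, R)
    >>> ranked = model.predict_one("S0000")  # leave-one-out for known substrates
    """

    def __init__(
        self,
        n_features: int = 500,
        learner: str = "linear",
        method: str = "weighted",
        threshold: float = DEFAULT_THRESHOLD,
        correlation_floor: float = DEFAULT_CORRELATION_FLOOR,
        random_state: int = 0,
    ):
        self.n_features = n_features
        self.learner = learner
        self.method = method
        self.threshold = threshold
        self.correlation_floor = correlation_floor
        self.random_state = random_state

    def fit(self, X: DescriptorMatrix, y: ReactionSet) -> "EnzymeReactionPredictor":
        """Fit on a descriptor matrix ``X`` and reaction set ``y``.

        Only the substrate rows referenced by ``y`` participate in
        normalization, pairing, ranking and model fitting; extra rows in
        ``X`` (e.g. candidate queries) are ignored.
        """
        substrates = sorted(y.substrates)
        missing = [s for s in substrates if s not in X.data.index]
        if missing:
            raise CoverageError(
                f"substrates without descriptor rows: {sorted(missing)[:10]}"
            )
        train = DescriptorMatrix(X.data.loc[substrates])
        self.normalization_ = fit_normalization(train)
        norm = apply_normalization(train, self.normalization_)
        pairs = build_pair_dataset(norm, y)
        self.ranking_ = rank_features(pairs, floor=self.correlation_floor)
        self.selected_features_ = select_top(
            self.ranking_, min(self.n_features, max(len(self.ranking_), 1))
        )
        self.pair_model_ = fit_pair_model(
            pairs,
            self.selected_features_,
            learner=self.learner,
            seed=self.random_state,
            normalization=self.normalization_,
        )
        self.reactions_ = y
        self.substrate_matrix_ = norm
        self.n_pairs_ = len(pairs.pairs)
        self.n_positive_pairs_ = pairs.n_positive
        return self

    def predict_one(
        self, query, query_id: str | None = None
    ) -> list[EnzymePrediction]:
        """Rank every enzyme for one query (id known to the model, or a
        raw descriptor row)."""
        return predict_enzymes(
            self.pair_model_,
            query,
            self.reactions_,
            self.substrate_matrix_,
            method=self.method,
            threshold=self.threshold,
            query_id=query_id,
        )

    def predict(self, X) -> pd.DataFrame:
        """Score every row of a (raw) descriptor matrix against every enzyme.

        Returns a tidy frame with one row per (query, enzyme):
        ``query_id, enzyme_id, integrated_score, decision, n_substrates``.
        """
        frame = X.data if isinstance(X, DescriptorMatrix) else pd.DataFrame(X)
        records = []
        for qid, row in frame.iterrows():
            for p in self.predict_one(row, query_id=str(qid)):
                records.append(
                    {
                        "query_id": p.query_id,
                        "enzyme_id": p.enzyme_id,
                        "integrated_score": p.score,
                        "decision": p.decision,
                        "n_substrates": p.n_substrates,
                    }
                )
        return pd.DataFrame.from_records(
            records,
            columns=[
                "query_id", "enzyme_id", "integrated_score", "decision", "n_substrates",
            ],
        )
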