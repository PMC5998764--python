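"""Collapse per-substrate pair scores into one integrated score per enzyme.

An enzyme with m known substrates gives a query molecule m individual
scores s_1..s_m.  Four integrators turn these into a single score p:

* ``mean`` — the arithmetic mean; drowns one strong match among many weak.
* ``max`` — the maximum; blind to how many substrates agree.
* ``noisy_or`` — 1 - prod(1 - s_i), the probability that at least one
  pairing reacts if the s_i were independent probabilities.
* ``weighted`` — the method's own integrator: starting from the mean, the
  scores at or above the mean pull the result upward in proportion to both
  their total excess and its root-mean-square,

      p = s_bar + [ sum_{s_i >= s_bar} (s_i - s_bar) ]
                  * sqrt( sum_i f(s_i - s_bar) / k ),
      f(d) = d^2 if s_i >= s_bar else 0,   k = #{ i : s_i >= s_bar },

  clipped to [0, 1].  It rewards a skewed score distribution: {0, 1}
  integrates to 0.75 while {0.5, 0.5} stays at 0.5, so one near-certain
  substrate match outranks two lukewarm ones.

A query is predicted to be catalyzed by an enzyme when its integrated
score reaches the decision threshold (default 0.75, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError
from .io_model import DescriptorMatrix, ReactionSet
from .pair_features import normalize_query_row
from .pairwise_model import PairModel, score_query_vs_enzyme

__all__ = [
    "EnzymePrediction",
    "integrate_mean",
    "integrate_max",
    "integrate_noisy_or",
    "integrate_weighted",
    "INTEGRATORS",
    "decide",
    "predict_enzymes",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.75


def _check_scores(s: Sequence[float], bounded: bool) -> np.ndarray:
    arr = np.asarray(list(s), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("cannot integrate an empty score list")
    if bounded and (np.any(arr < 0) or np.any(arr > 1)):
        raise DomainError(f"scores must lie in [0,1], got {arr[(arr < 0) | (arr > 1)]}")
    return arr


def integrate_mean(s: Sequence[float]) -> float:
    """Simple average of the individual scores."""
    return float(_check_scores(s, bounded=False).mean())


def integrate_max(s: Sequence[float]) -> float:
    """Maximum of the individual scores."""
    return float(_check_scores(s, bounded=False).max())


def integrate_noisy_or(s: Sequence[float]) -> float:
    """Probability-based integration: 1 - prod(1 - s_i)."""
    arr = _check_scores(s, bounded=True)
    return float(1.0 - np.prod(1.0 - arr))


def integrate_weighted(s: Sequence[float]) -> float:
    """Weighted integration favouring scores above the mean (see module docs).

    The sum of deviations runs over the scores at or above the mean (the
    full signed sum would cancel to zero); k counts those same scores,
    ties at the mean included.  Equal scores integrate to their common
    value; the result never falls below the mean and is clipped to [0,1].
    """
    arr = _check_scores(s, bounded=True)
    s_bar = float(arr.mean())
    above = arr >= s_bar
    k = int(above.sum())
    if k == 0:
        # only reachable through floating rounding (mean of a constant
        # list can land one ulp above every element); all deviations are
        # then negligible and the integrated score is the mean
        return s_bar
    dev = arr[above] - s_bar
    p = s_bar + float(dev.sum()) * float(np.sqrt(np.sum(dev**2) / k))
    return float(min(max(p, 0.0), 1.0))


INTEGRATORS: dict[str, Callable[[Sequence[float]], float]] = {
    "mean": integrate_mean,
    "max": integrate_max,
    "noisy_or": integrate_noisy_or,
    "weighted": integrate_weighted,
}


def decide(p: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Catalysis decision: integrated score at or above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold must lie in [0,1], got {threshold}")
    return p >= threshold


@dataclass
class EnzymePrediction:
    """Integrated score(s) and decision for one (query, enzyme) pair."""

    enzyme_id: str
    query_id: str
    scores: list[float]
    integrated: dict[str, float]
    method: str
    threshold: float
    decision: bool = field(init=False)

    def __post_init__(self) -> None:
        self.decision = decide(self.integrated[self.method], self.threshold)

    @property
    def score(self) -> float:
        return self.integrated[self.method]

    @property
    def n_substrates(self) -> int:
        return len(self.scores)


def predict_enzymes(
    M: PairModel,
    query,
    R: ReactionSet,
    D: DescriptorMatrix,
    method: str = "weighted",
    threshold: float = DEFAULT_THRESHOLD,
    query_id: str | None = None,
) -> list[EnzymePrediction]:
    """Score a query molecule against every enzyme in the reaction set.

    ``query`` is either a molecule id present in ``D`` or a raw descriptor
    row (:class:`pandas.Series`).  ``D`` may be raw or already normalized
    with the model's parameters; raw matrices are normalized on the fly.
    If the query is itself a known substrate it is excluded from every
    enzyme's substrate list before scoring.  Enzymes whose substrate list
    becomes empty (no descriptor coverage, or only the query itself) are
    omitted.  Results are sorted by integrated score descending, ties by
    enzyme id.
    """
    if method not in INTEGRATORS:
        raise DomainError(f"unknown integration method {method!r}")
    params = M.normalization
    if D.normalization is None and params is not None:
        from .pair_features import apply_normalization

        D = apply_normalization(D, params)

    if isinstance(query, str):
        qid = query
        q_norm = D.row(query)
    else:
        q_raw = pd.Series(query, dtype=float)
        qid = query_id or str(getattr(query, "name", None) or "query")
        q_norm = normalize_query_row(q_raw, params) if params is not None else q_raw

    q_vec = q_norm[M.feature_names].to_numpy(dtype=float)
    sub_frame = D.data
    preds: list[EnzymePrediction] = []
    for enzyme, subs in sorted(R.enzyme_to_substrates().items()):
        keep = sorted(s for s in subs if s != qid and s in sub_frame.index)
        if not keep:
            continue
        rows = sub_frame.loc[keep, M.feature_names]
        scores = score_query_vs_enzyme(M, q_vec, rows)
        integrated = {name: fn(scores) for name, fn in INTEGRATORS.items()}
        preds.append(
            EnzymePrediction(
                enzyme_id=enzyme,
                query_id=qid,
                scores=scores,
                integrated=integrated,
                method=method,
                threshold=threshold,
            )
        )
    preds.sort(key=lambda p: (-p.score, p.enzyme_id))
    return preds
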