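"""Rank pair features by point-biserial correlation with the binary label.

The relevance score of a difference feature is the point-biserial
correlation

    r_pb = (M1 - M0) / s_n * sqrt(n1 * n0 / n^2)

where M1/M0 are the class-conditional feature means, n1/n0 the class
sizes, n = n1 + n0, and s_n the *population* (divide-by-n) standard
deviation of the feature.  This is algebraically the Pearson correlation
between the feature and the 0/1 label.  Features are ordered by |r_pb|
and the top n kept; features with |r_pb| below a small floor (default
0.01) carry essentially no signal and are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .errors import (
    DegenerateLabelsError,
    DomainError,
    InsufficientDataError,
    SchemaError,
)
from .pair_features import PairFeatureSet

__all__ = [
    "RankedFeatures",
    "PointBiserialSelector",
    "point_biserial",
    "rank_features",
    "select_top",
]

DEFAULT_CORRELATION_FLOOR = 0.01


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    vals = set(np.unique(labels))
    if not vals <= {0, 1}:
        raise SchemaError(f"labels must be from {{0,1}}, found {sorted(vals)}")
    return labels.astype(float)


def point_biserial(x, labels) -> float:
    """Point-biserial correlation between a feature and a 0/1 label.

    Uses the population standard deviation.  Returns 0 for zero-variance
    features and when one class is empty (such features carry no usable
    signal and route to exclusion rather than erroring).
    """
    x = np.asarray(x, dtype=float)
    y = _validate_labels(labels)
    if x.shape != y.shape:
        raise SchemaError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 observations, got {n}")
    n1 = int(y.sum())
    n0 = n - n1
    s_n = float(x.std(ddof=0))
    if s_n == 0.0 or n1 == 0 or n0 == 0:
        return 0.0
    m1 = float(x[y == 1].mean())
    m0 = float(x[y == 0].mean())
    return (m1 - m0) / s_n * np.sqrt(n1 * n0 / n**2)


def _point_biserial_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized r_pb for every column of X against the same 0/1 label."""
    n = X.shape[0]
    n1 = int(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelsError("labels contain a single class")
    s_n = X.std(axis=0, ddof=0)
    m1 = X[y == 1].mean(axis=0)
    m0 = X[y == 0].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (m1 - m0) / s_n * np.sqrt(n1 * n0 / n**2)
    r[s_n == 0] = 0.0
    return r


@dataclass(frozen=True)
class RankedFeatures:
    """Features ordered by decreasing |r_pb|, plus the excluded tail.

    ``ranked`` holds ``(descriptor_name, r_pb)`` sorted by decreasing
    |r_pb| (ties broken by name); ``excluded`` holds the features whose
    |r_pb| fell below the exclusion floor, in the same order convention.
    """

    ranked: tuple[tuple[str, float], ...]
    excluded: tuple[tuple[str, float], ...]
    floor: float = DEFAULT_CORRELATION_FLOOR

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.ranked]

    def __len__(self) -> int:
        return len(self.ranked)


def rank_features(
    P: PairFeatureSet, floor: float = DEFAULT_CORRELATION_FLOOR
) -> RankedFeatures:
    """Rank every descriptor column of a pair dataset by |r_pb|."""
    y = _validate_labels(P.labels)
    if len(P.pairs) == 0:
        raise InsufficientDataError("empty pair dataset")
    r = _point_biserial_columns(P.features.astype(float), y)
    order = sorted(
        zip(P.feature_names, r), key=lambda t: (-abs(t[1]), t[0])
    )
    ranked = tuple((n, float(v)) for n, v in order if abs(v) >= floor)
    excluded = tuple((n, float(v)) for n, v in order if abs(v) < floor)
    return RankedFeatures(ranked=ranked, excluded=excluded, floor=floor)


def select_top(R: RankedFeatures, n: int) -> list[str]:
    """The names of the min(n, available) best-ranked features."""
    if n < 1:
        raise DomainError(f"feature count must be >= 1, got {n}")
    return R.names[:n]


class PointBiserialSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector keeping the top-n |r_pb| columns.

    Parameters
    ----------
    n_features : int, default 500
        Number of top-ranked features to retain.
    floor : float, default 0.01
        Exclusion floor on |r_pb|; columns below it are never selected.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features_in_,)
        r_pb per input column, in input order.
    ranking_ : RankedFeatures
        Full ordering with the excluded tail.
    """

    def __init__(self, n_features: int = 500, floor: float = DEFAULT_CORRELATION_FLOOR):
        self.n_features = n_features
        self.floor = floor

    def fit(self, X, y) -> "PointBiserialSelector":
        import pandas as pd

        if self.n_features < 1:
            raise DomainError(f"n_features must be >= 1, got {self.n_features}")
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        yv = _validate_labels(y)
        r = _point_biserial_columns(Xv, yv)
        order = sorted(zip(names, r), key=lambda t: (-abs(t[1]), t[0]))
        self.scores_ = r
        self.ranking_ = RankedFeatures(
            ranked=tuple((n, float(v)) for n, v in order if abs(v) >= self.floor),
            excluded=tuple((n, float(v)) for n, v in order if abs(v) < self.floor),
            floor=self.floor,
        )
        self.selected_names_ = select_top(self.ranking_, self.n_features)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xv.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        chosen = set(self.selected_names_)
        return np.asarray([n in chosen for n in self.feature_names_in_])
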