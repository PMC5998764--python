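"""Build the supervised pair dataset: absolute descriptor differences for
every unordered substrate pair, labeled 1 when the pair shares an enzyme.

The learning instance of this method is not a molecule but a *pair* of
molecules.  For substrates ``a`` and ``b`` with z-scored descriptor vectors
``x_a`` and ``x_b``, the feature vector is the element-wise absolute
difference ``|x_a - x_b|`` and the label is 1 exactly when some enzyme
catalyzes both.  Because substrates of the same enzyme tend to be
physico-chemically similar, positive pairs concentrate near the origin of
difference space, which is the signal the downstream linear model learns.

Descriptors are normalized (z-scored per column, population standard
deviation) *before* subtraction, with parameters fitted on the training
substrate matrix only, so query molecules can be mapped into the same space
at prediction time without leakage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    CoverageError,
    DomainError,
    InsufficientDataError,
    SchemaError,
)
from .io_model import DescriptorMatrix, ReactionSet

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "DescriptorNormalizer",
    "PairFeatureSet",
    "fit_normalization",
    "apply_normalization",
    "pair_feature",
    "build_pair_dataset",
    "count_pairs",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-descriptor z-scoring parameters fitted on a reference matrix.

    ``means``/``sds`` are indexed by retained descriptor name; ``dropped``
    lists descriptors removed for zero variance or for containing missing
    values in the fitting matrix.  Stored standard deviations are strictly
    positive (population convention, divide by n).
    """

    means: pd.Series
    sds: pd.Series
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            bad = list(self.sds.index[self.sds <= 0])
            raise DomainError(f"non-positive standard deviations for {bad}")

    @property
    def retained(self) -> list[str]:
        return list(self.means.index)

    def to_dict(self) -> dict:
        return {
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            means=pd.Series(d["means"], dtype=float),
            sds=pd.Series(d["sds"], dtype=float),
            dropped=tuple(d.get("dropped", ())),
        )


class DescriptorNormalizer(TransformerMixin, BaseEstimator):
    """Z-score descriptor columns with the population standard deviation.

    scikit-learn-style transformer over :class:`DescriptorMatrix` (or a
    plain DataFrame).  Zero-variance columns and columns containing missing
    values in the fitting matrix are dropped, not scaled; their names are
    recorded on ``params_.dropped``.

    Attributes
    ----------
    params_ : NormalizationParams
        Fitted means/standard deviations for the retained columns.
    """

    def __init__(self) -> None:
        pass

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        return X.data if isinstance(X, DescriptorMatrix) else pd.DataFrame(X)

    def fit(self, X, y=None) -> "DescriptorNormalizer":
        df = self._frame(X)
        if len(df) < 2:
            raise InsufficientDataError(
                f"normalization needs at least 2 rows, got {len(df)}"
            )
        has_missing = df.columns[df.isna().any()]
        means = df.mean()
        sds = df.std(ddof=0)  # population convention
        zero_var = df.columns[(sds == 0) | sds.isna()]
        dropped = sorted(set(has_missing) | set(zero_var))
        if dropped:
            logger.info(
                "dropping %d descriptor columns (%d with missing values, "
                "%d zero-variance)",
                len(dropped), len(has_missing), len(zero_var),
            )
        keep = [c for c in df.columns if c not in set(dropped)]
        self.params_ = NormalizationParams(
            means=means[keep], sds=sds[keep], dropped=tuple(dropped)
        )
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        p = self.params_
        df = self._frame(X)
        missing = [c for c in p.retained if c not in df.columns]
        if missing:
            raise SchemaError(f"matrix lacks normalized columns: {missing}")
        return (df[p.retained] - p.means) / p.sds

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.params_.retained, dtype=object)


def fit_normalization(D: DescriptorMatrix) -> NormalizationParams:
    """Fit per-column z-scoring parameters on a descriptor matrix."""
    return DescriptorNormalizer().fit(D).params_


def apply_normalization(D: DescriptorMatrix, P: NormalizationParams) -> DescriptorMatrix:
    """Apply previously fitted z-scoring parameters (never refit).

    Dropped columns are removed; the result records ``P`` as its
    normalization state.  Values outside the fitting range map linearly.
    """
    norm = DescriptorNormalizer()
    norm.params_ = P
    return DescriptorMatrix(norm.transform(D), normalization=P)


def normalize_query_row(row: pd.Series, P: NormalizationParams) -> pd.Series:
    """Map one raw descriptor row into the fitted normalized space."""
    missing = [c for c in P.retained if c not in row.index]
    if missing:
        raise SchemaError(f"query row lacks descriptor columns: {missing}")
    return (row[P.retained] - P.means) / P.sds


def pair_feature(a_row, b_row) -> np.ndarray:
    """Element-wise absolute difference of two aligned descriptor vectors.

    Symmetric in its arguments; the zero vector for identical molecules.
    """
    a = np.asarray(a_row, dtype=float)
    b = np.asarray(b_row, dtype=float)
    if a.shape != b.shape:
        raise SchemaError(f"descriptor length mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def count_pairs(n: int) -> int:
    """Number of unordered pairs among n molecules: n(n-1)/2."""
    if n < 0:
        raise DomainError(f"substrate count must be non-negative, got {n}")
    return n * (n - 1) // 2


@dataclass
class PairFeatureSet:
    """Unordered substrate pairs with difference features and binary labels.

    ``pairs[i]`` is ``(a, b)`` with ``a < b`` lexicographically; row ``i``
    of ``features`` is ``|x_a - x_b|`` and ``labels[i]`` is 1 when the two
    substrates share at least one enzyme.
    """

    pairs: list[tuple[str, str]]
    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.pairs)
        if self.features.shape != (n, len(self.feature_names)):
            raise SchemaError(
                f"feature matrix shape {self.features.shape} does not match "
                f"{n} pairs x {len(self.feature_names)} descriptors"
            )
        if self.labels.shape != (n,):
            raise SchemaError("labels length does not match pair count")
        lab = set(np.unique(self.labels))
        if not lab <= {0, 1}:
            raise SchemaError(f"labels must be binary, found {sorted(lab)}")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def frame(self) -> pd.DataFrame:
        """Tabular view: substrate_a, substrate_b, label, then features."""
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "substrate_b", [b for _, b in self.pairs])
        df.insert(0, "substrate_a", [a for a, _ in self.pairs])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairFeatureSet":
        meta = ["substrate_a", "substrate_b", "label"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise SchemaError(f"pair table lacks columns {missing}")
        names = [c for c in df.columns if c not in meta]
        return cls(
            pairs=list(zip(df["substrate_a"].astype(str), df["substrate_b"].astype(str))),
            features=df[names].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            feature_names=names,
        )


def build_pair_dataset(
    D: DescriptorMatrix,
    R: ReactionSet,
    columns: list[str] | None = None,
) -> PairFeatureSet:
    """Build the exhaustive pair dataset over the substrates of ``R``.

    ``D`` should be normalized already (the builder does not normalize).
    One row per unordered substrate pair, ordered by the canonical sorted
    pair key; label 1 iff the substrates share at least one enzyme.

    ``columns`` restricts the materialized feature columns (useful once a
    feature subset has been selected); pair order and labels are unchanged,
    and the materialized columns equal those of the full computation.
    """
    substrates = sorted(R.substrates)
    missing = [s for s in substrates if s not in D.data.index]
    if missing:
        raise CoverageError(
            f"{len(missing)} substrates lack descriptor rows: {sorted(missing)[:10]}"
        )
    names = list(D.data.columns) if columns is None else list(columns)
    unknown = [c for c in names if c not in D.data.columns]
    if unknown:
        raise SchemaError(f"unknown descriptor columns requested: {unknown}")

    X = D.data.loc[substrates, names].to_numpy(dtype=float)
    n = len(substrates)
    idx_a, idx_b = np.triu_indices(n, k=1)
    feats = np.abs(X[idx_a] - X[idx_b])

    s2e = R.substrate_to_enzymes()
    enzymes = {e: i for i, e in enumerate(sorted(R.enzymes))}
    member = np.zeros((n, len(enzymes)), dtype=bool)
    for i, s in enumerate(substrates):
        for e in s2e.get(s, ()):  # every substrate of R has >=1 enzyme
            member[i, enzymes[e]] = True
    shares = (member @ member.T) > 0
    labels = shares[idx_a, idx_b].astype(int)

    pairs = [(substrates[i], substrates[j]) for i, j in zip(idx_a, idx_b)]
    return PairFeatureSet(pairs=pairs, features=feats, labels=labels, feature_names=names)
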