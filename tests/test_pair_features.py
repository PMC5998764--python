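"""Normalization, pair-feature construction and the exhaustive pair dataset."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from enzypred.errors import (
    CoverageError,
    DomainError,
    InsufficientDataError,
    SchemaError,
)
from enzypred.io_model import DescriptorMatrix, ReactionSet
from enzypred.pair_features import (
    apply_normalization,
    build_pair_dataset,
    count_pairs,
    fit_normalization,
    pair_feature,
)


def _dm(values, columns=None, index=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    columns = columns or [f"d{j}" for j in range(values.shape[1])]
    index = index or [f"m{i}" for i in range(values.shape[0])]
    return DescriptorMatrix(pd.DataFrame(values, index=index, columns=columns))


class TestNormalization:
    def test_two_point_column(self):
        params = fit_normalization(_dm([[0.0], [2.0]]))
        assert params.means["d0"] == pytest.approx(1.0)
        assert params.sds["d0"] == pytest.approx(1.0)
        normed = apply_normalization(_dm([[0.0], [2.0]]), params)
        assert normed.data["d0"].tolist() == pytest.approx([-1.0, 1.0])

    def test_constant_column_dropped(self):
        params = fit_normalization(_dm([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]]))
        assert "d0" in params.dropped
        assert params.retained == ["d1"]

    def test_population_sd_convention(self):
        params = fit_normalization(_dm([[1.0], [2.0], [3.0], [4.0]]))
        assert params.means["d0"] == pytest.approx(2.5)
        assert params.sds["d0"] == pytest.approx(np.sqrt(1.25))  # 1.1180

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_normalization(_dm([[1.0, 2.0]]))

    def test_missing_value_column_dropped(self):
        dm = _dm([[1.0, 1.0], [np.nan, 2.0], [3.0, 3.0]])
        params = fit_normalization(dm)
        assert "d0" in params.dropped

    def test_apply_self_gives_zero_mean_unit_sd(self, rng):
        dm = _dm(rng.normal(size=(20, 5)))
        params = fit_normalization(dm)
        normed = apply_normalization(dm, params)
        assert np.allclose(normed.data.mean(), 0.0, atol=1e-9)
        assert np.allclose(normed.data.std(ddof=0), 1.0, atol=1e-9)
        assert normed.normalization is params

    def test_apply_is_linear_outside_fit_range(self):
        params = fit_normalization(_dm([[1.0], [2.0], [3.0], [4.0]]))
        out = apply_normalization(_dm([[10.0]]), params)
        assert out.data.iloc[0, 0] == pytest.approx((10 - 2.5) / np.sqrt(1.25))
        assert out.data.iloc[0, 0] == pytest.approx(6.7082, abs=1e-4)

    def test_stored_params_used_not_refit(self):
        params = fit_normalization(_dm([[0.0], [2.0]]))  # mean 1, sd 1
        out = apply_normalization(_dm([[3.0], [5.0]]), params)
        assert out.data["d0"].tolist() == pytest.approx([2.0, 4.0])

    def test_missing_retained_column_is_schema_error(self):
        params = fit_normalization(_dm([[0.0], [2.0]]))
        with pytest.raises(SchemaError):
            apply_normalization(_dm([[1.0]], columns=["other"]), params)


class TestPairFeature:
    def test_elementwise_absolute_difference(self):
        assert pair_feature([1, 3], [2, 1]).tolist() == [1, 2]

    def test_identical_vectors_give_zero(self):
        x = np.array([0.3, -1.2, 4.0])
        assert pair_feature(x, x).tolist() == [0, 0, 0]

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            pair_feature([1, 2], [1, 2, 3])

    @settings(max_examples=100, derandomize=True)
    @given(
        arrays(float, 8, elements=st.floats(-50, 50)),
        arrays(float, 8, elements=st.floats(-50, 50)),
    )
    def test_symmetric_in_arguments(self, a, b):
        assert pair_feature(a, b).tolist() == pair_feature(b, a).tolist()


class TestCountPairs:
    @pytest.mark.parametrize(
        "n, expected", [(0, 0), (1, 0), (2, 1), (100, 4950), (1879, 1_764_381)]
    )
    def test_closed_form(self, n, expected):
        assert count_pairs(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            count_pairs(-1)


def _brute_force_positive_pairs(reactions):
    """O(n^2) oracle: pairs of substrates sharing at least one enzyme."""
    subs = sorted({s for _, s in reactions})
    enz = {s: {e for e, t in reactions if t == s} for s in subs}
    return {
        (a, b)
        for a, b in itertools.combinations(subs, 2)
        if enz[a] & enz[b]
    }


class TestBuildPairDataset:
    def test_three_substrate_example(self, tiny_matrix, tiny_reactions):
        params = fit_normalization(tiny_matrix)
        pairs = build_pair_dataset(
            apply_normalization(tiny_matrix, params), tiny_reactions
        )
        assert pairs.pairs == [("a", "b"), ("a", "c"), ("b", "c")]
        assert pairs.labels.tolist() == [1, 0, 0]

    def test_row_count_is_n_choose_2(self, separated_dataset):
        D, R, _ = separated_dataset
        params = fit_normalization(DescriptorMatrix(D.data.loc[sorted(R.substrates)]))
        pairs = build_pair_dataset(apply_normalization(D, params), R)
        assert len(pairs.pairs) == count_pairs(len(R.substrates))

    def test_features_nonnegative_and_symmetric_order(self, separated_dataset):
        D, R, _ = separated_dataset
        params = fit_normalization(DescriptorMatrix(D.data.loc[sorted(R.substrates)]))
        pairs = build_pair_dataset(apply_normalization(D, params), R)
        assert (pairs.features >= 0).all()
        assert all(a < b for a, b in pairs.pairs)

    def test_positive_count_matches_brute_force_oracle(self, rng):
        # 20 substrates, 5 enzymes, random bipartite relation
        reactions = {
            (f"E{rng.integers(5)}", f"s{idx:02d}")
            for idx in range(20)
        }
        # give some substrates a second enzyme
        reactions |= {
            (f"E{rng.integers(5)}", f"s{rng.integers(20):02d}") for _ in range(6)
        }
        R = ReactionSet.from_pairs(reactions)
        D = _dm(
            rng.normal(size=(20, 4)),
            index=[f"s{idx:02d}" for idx in range(20)],
        )
        params = fit_normalization(D)
        pairs = build_pair_dataset(apply_normalization(D, params), R)
        oracle = _brute_force_positive_pairs(reactions)
        got = {p for p, lab in zip(pairs.pairs, pairs.labels) if lab == 1}
        assert got == oracle

    def test_column_selected_equals_full_computation(self, separated_dataset):
        D, R, _ = separated_dataset
        params = fit_normalization(DescriptorMatrix(D.data.loc[sorted(R.substrates)]))
        normed = apply_normalization(D, params)
        full = build_pair_dataset(normed, R)
        cols = full.feature_names[:7]
        part = build_pair_dataset(normed, R, columns=cols)
        assert part.pairs == full.pairs
        assert part.labels.tolist() == full.labels.tolist()
        idx = [full.feature_names.index(c) for c in cols]
        assert np.array_equal(part.features, full.features[:, idx])

    def test_missing_substrate_is_coverage_error(self, tiny_matrix):
        R = ReactionSet.from_pairs([("E1", "a"), ("E1", "zzz")])
        with pytest.raises(CoverageError, match="zzz"):
            build_pair_dataset(tiny_matrix, R)

    def test_frame_round_trip(self, tiny_matrix, tiny_reactions):
        from enzypred.pair_features import PairFeatureSet

        pairs = build_pair_dataset(tiny_matrix, tiny_reactions)
        again = PairFeatureSet.from_frame(pairs.frame())
        assert again.pairs == pairs.pairs
        assert np.allclose(again.features, pairs.features)
        assert again.labels.tolist() == pairs.labels.tolist()
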