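"""Ranking metrics, threshold scanning and enzyme-wise cross-validation."""

import numpy as np
import pytest

from enzypred.errors import DegenerateLabelsError, DomainError, EvaluationError
from enzypred.evaluation import (
    auc,
    confusion_metrics,
    cross_validate,
    default_threshold_grid,
    fit_fold_model,
    partition_enzymes,
    threshold_scan,
)
from enzypred.io_model import DescriptorMatrix, ReactionSet


def concordance_auc(scores, labels):
    """Exhaustive pairwise-comparison oracle; ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_full_tie_is_half(self):
        assert auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_concordance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 30))
            scores = np.round(rng.uniform(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if len(set(labels)) < 2:
                continue
            assert auc(scores, labels) == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        assert auc(scores, labels) == pytest.approx(
            auc(np.exp(3 * scores), labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc([0.1, 0.2], [1, 1])


class TestConfusionMetrics:
    def test_perfect_predictor(self):
        rep = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert (rep.sen, rep.spe, rep.ppv, rep.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_all_negative_predictions(self):
        rep = confusion_metrics([0.1, 0.2, 0.3], [1, 0, 1], 0.9)
        assert rep.sen == 0.0
        assert rep.spe == 1.0
        assert "ppv" in rep.flags  # no positive prediction -> zero denominator

    def test_hand_computed_mcc(self):
        # TP=6, FP=1, TN=2, FN=1:
        # MCC = (6*2 - 1*1)/sqrt(7*7*3*3) = 11/21
        scores = [1] * 6 + [1] + [0] * 2 + [0]
        labels = [1] * 6 + [0] + [0] * 2 + [1]
        rep = confusion_metrics(scores, labels, 0.5)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (6, 1, 2, 1)
        assert rep.mcc == pytest.approx(11 / 21, abs=1e-12)

    def test_matches_sklearn_mcc(self, rng):
        from sklearn.metrics import matthews_corrcoef

        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, size=60)
        rep = confusion_metrics(scores, labels, 0.5)
        preds = (scores >= 0.5).astype(int)
        assert rep.mcc == pytest.approx(
            matthews_corrcoef(labels, preds), abs=1e-12
        )

    def test_metric_ranges(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        rep = confusion_metrics(scores, labels, 0.4)
        assert 0 <= rep.sen <= 1 and 0 <= rep.spe <= 1 and 0 <= rep.ppv <= 1
        assert -1 <= rep.mcc <= 1

    def test_sen_spe_monotone_in_threshold(self, rng):
        scores = rng.uniform(size=80)
        labels = rng.integers(0, 2, size=80)
        grid = default_threshold_grid()
        sens = [confusion_metrics(scores, labels, t).sen for t in grid]
        spes = [confusion_metrics(scores, labels, t).spe for t in grid]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spes, spes[1:]))


class TestThresholdScan:
    def test_scores_equal_labels(self):
        labels = [0, 1, 0, 1, 1, 0]
        curve = threshold_scan(labels, labels)
        # every threshold in (0,1] separates perfectly; 0 predicts all positive
        assert np.allclose(curve.mcc[1:], 1.0)
        assert curve.best_threshold == pytest.approx(0.05)

    def test_constant_scores_flat_zero(self):
        curve = threshold_scan([0.4] * 10, [0, 1] * 5)
        assert np.allclose(curve.mcc, 0.0)

    def test_curve_matches_pointwise_recomputation(self, rng):
        scores = rng.uniform(size=12)
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 0, 1, 0, 0])
        grid = default_threshold_grid()
        curve = threshold_scan(scores, labels, grid)
        oracle = [confusion_metrics(scores, labels, t).mcc for t in grid]
        assert curve.mcc == pytest.approx(oracle, abs=1e-12)

    def test_best_is_lowest_argmax(self):
        curve = threshold_scan([1, 1, 0, 0], [1, 1, 0, 0])
        idx = np.flatnonzero(curve.mcc == curve.mcc.max())
        assert curve.best_threshold == curve.thresholds[idx[0]]

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(DomainError):
            threshold_scan([0.1, 0.9], [0, 1], grid=[0.5, 0.5])


class TestPartitionEnzymes:
    def _reaction_set(self, n_enzymes):
        return ReactionSet.from_pairs([(f"E{i}", f"s{i}") for i in range(n_enzymes)])

    def test_one_enzyme_per_fold(self):
        R = self._reaction_set(20)
        folds = partition_enzymes(R, 20, seed=0)
        assert sorted(folds.values()) == list(range(20))

    def test_deterministic_given_seed(self):
        R = self._reaction_set(30)
        assert partition_enzymes(R, 5, seed=7) == partition_enzymes(R, 5, seed=7)
        assert partition_enzymes(R, 5, seed=7) != partition_enzymes(R, 5, seed=8)

    def test_pigeonhole_sizes(self):
        R = self._reaction_set(103)
        folds = partition_enzymes(R, 20, seed=1)
        sizes = np.bincount(list(folds.values()), minlength=20)
        assert set(sizes) == {5, 6}
        assert sizes.sum() == 103
        assert (sizes == 6).sum() == 3

    def test_k_out_of_range(self):
        R = self._reaction_set(5)
        with pytest.raises(DomainError):
            partition_enzymes(R, 1, seed=0)
        with pytest.raises(DomainError):
            partition_enzymes(R, 6, seed=0)


class TestCrossValidate:
    def test_two_fold_smoke(self, rng):
        # four disjoint substrate clusters, one per enzyme, two folds;
        # each training half keeps two enzymes so both pair classes exist
        rows, pairs = {}, []
        for e, center in (("E0", -6.0), ("E1", -2.0), ("E2", 2.0), ("E3", 6.0)):
            for j in range(5):
                sid = f"{e}s{j}"
                rows[sid] = center + rng.normal(0, 0.1, size=8)
                pairs.append((e, sid))
        import pandas as pd

        D = DescriptorMatrix(
            pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"d{j}" for j in range(8)])
        )
        R = ReactionSet.from_pairs(pairs)
        rep = cross_validate(D, R, k=2, n_features=8, seed=0)
        assert len(rep.per_fold) == 2
        assert rep.auc is not None

    def test_separated_clusters_recovered(self, separated_dataset):
        D, R, _ = separated_dataset
        rep = cross_validate(D, R, k=5, n_features=40, seed=3)
        assert rep.auc >= 0.85

    def test_fold_fit_blind_to_held_out_substrates(self, separated_dataset):
        # deleting the held-out substrate rows from the descriptor input
        # must leave the fitted fold model bit-identical
        D, R, _ = separated_dataset
        assignment = partition_enzymes(R, 5, seed=2)
        test_enzymes = {e for e, f in assignment.items() if f == 0}
        held_out = {
            s for s, es in R.substrate_to_enzymes().items() if es <= test_enzymes
        }
        assert held_out  # the audit is vacuous otherwise
        full = fit_fold_model(D, R, test_enzymes, n_features=40)
        trimmed_D = DescriptorMatrix(D.data.drop(index=sorted(held_out)))
        trimmed = fit_fold_model(trimmed_D, R, test_enzymes, n_features=40)
        assert trimmed.selected_features_ == full.selected_features_
        assert np.array_equal(trimmed.pair_model_.coef, full.pair_model_.coef)
        assert trimmed.pair_model_.intercept == full.pair_model_.intercept
        assert np.array_equal(
            trimmed.normalization_.means.to_numpy(),
            full.normalization_.means.to_numpy(),
        )

    def test_all_folds_unevaluable_raises(self, rng):
        # one substrate per enzyme: held-out enzymes have no reference left
        import pandas as pd

        rows = {f"s{i}": rng.normal(size=4) for i in range(6)}
        D = DescriptorMatrix(
            pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"d{j}" for j in range(4)])
        )
        R = ReactionSet.from_pairs([(f"E{i}", f"s{i}") for i in range(6)])
        with pytest.raises((EvaluationError, DegenerateLabelsError)):
            cross_validate(D, R, k=2, n_features=4, seed=0)

    def test_report_serializes(self, separated_dataset):
        import json

        D, R, _ = separated_dataset
        rep = cross_validate(D, R, k=5, n_features=20, seed=5)
        doc = json.loads(json.dumps(rep.to_dict()))
        assert doc["tp"] + doc["fp"] + doc["tn"] + doc["fn"] > 0
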