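import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ademiner import evaluation as ev
from ademiner.records import Label

from conftest import make_sentence


def _records(n_ade, n_noade):
    return [make_sentence(f"a{i}", ["x"], Label.ADE) for i in range(n_ade)] + [
        make_sentence(f"n{i}", ["y"], Label.NO_ADE) for i in range(n_noade)
    ]


class MajorityPipeline(ev.Pipeline):
    def fit(self, records):
        labels = [r.label for r in records]
        self.majority = max(set(labels), key=labels.count)
        return self

    def predict(self, records):
        return [self.majority] * len(records), np.zeros(len(records))


class OraclePipeline(ev.Pipeline):
    def fit(self, records):
        return self

    def predict(self, records):
        labels = [r.label for r in records]
        scores = np.array([1.0 if l is Label.ADE else -1.0 for l in labels])
        return labels, scores


class TestStratifiedSplit:
    def test_preserves_class_proportions(self):
        train, test = ev.stratified_split(_records(40, 60), train_frac=0.75, seed=0)
        n_ade_train = sum(r.label is Label.ADE for r in train)
        n_no_train = sum(r.label is Label.NO_ADE for r in train)
        assert abs(n_ade_train - 30) <= 1 and abs(n_no_train - 45) <= 1
        assert len(train) + len(test) == 100

    def test_deterministic_per_seed(self):
        recs = _records(20, 30)
        s1 = ev.stratified_split(recs, seed=5)
        s2 = ev.stratified_split(recs, seed=5)
        assert [r.sent_id for r in s1[0]] == [r.sent_id for r in s2[0]]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ev.stratified_split(_records(5, 5), train_frac=1.5)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(2, 40), st.integers(2, 40), st.integers(0, 10))
    def test_partition_property(self, n_ade, n_noade, seed):
        recs = _records(n_ade, n_noade)
        train, test = ev.stratified_split(recs, seed=seed)
        train_ids = {r.sent_id for r in train}
        test_ids = {r.sent_id for r in test}
        assert train_ids | test_ids == {r.sent_id for r in recs}
        assert train_ids & test_ids == set()


class TestKFoldCV:
    def test_majority_pipeline_accuracy(self):
        result = ev.kfold_cv(_records(30, 70), MajorityPipeline, k=4, seed=0)
        assert result.mean_accuracy == pytest.approx(0.70, abs=0.02)

    def test_oracle_pipeline_is_perfect(self):
        result = ev.kfold_cv(_records(20, 20), OraclePipeline, k=4, seed=0)
        assert all(f.metrics.accuracy == 1.0 for f in result.folds)
        assert all(f.auc == 1.0 for f in result.folds)

    def test_each_record_tested_exactly_once(self):
        recs = _records(13, 17)
        seen = []

        class Collector(OraclePipeline):
            def predict(self, records):
                seen.extend(r.sent_id for r in records)
                return super().predict(records)

        ev.kfold_cv(recs, Collector, k=4, seed=1)
        assert sorted(seen) == sorted(r.sent_id for r in recs)

    def test_class_too_small_for_folds(self):
        with pytest.raises(ValueError, match="fewer than"):
            ev.kfold_cv(_records(2, 50), MajorityPipeline, k=4, seed=0)


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 0, 0, 5), (1.0, 1.0, 1.0)),
            ((0, 0, 5, 5), (0.5, 0.0, 0.0)),
            ((93, 7, 7, 93), (0.93, 0.93, 0.93)),
        ],
    )
    def test_closed_form(self, counts, expected):
        m = ev.compute_metrics(ev.ConfusionCounts(*counts))
        assert (m.accuracy, m.precision, m.recall) == pytest.approx(expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        true = [Label.ADE if b else Label.NO_ADE for b in rng.integers(0, 2, 50)]
        pred = [Label.ADE if b else Label.NO_ADE for b in rng.integers(0, 2, 50)]
        m1 = ev.compute_metrics(ev.confusion(true, pred))
        perm = rng.permutation(50)
        m2 = ev.compute_metrics(
            ev.confusion([true[i] for i in perm], [pred[i] for i in perm])
        )
        assert m1 == m2


def auc_bruteforce(scores, labels):
    """All-pairs comparison: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, curve = ev.roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0
        assert (0.0, 1.0) in curve

    def test_all_ties_give_half(self):
        auc, _ = ev.roc_auc([0.5] * 6, [True, False, True, False, True, False])
        assert auc == 0.5

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            ev.roc_auc([0.1, 0.2], [True, True])

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            auc, _ = ev.roc_auc(scores, labels)
            assert auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)


class TestPairedTTest:
    def test_identical_lists(self):
        assert ev.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_difference_signaled(self):
        t, p = ev.paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert t == math.inf and p == 0.0

    def test_hand_computed_four_pairs(self):
        a = [0.90, 0.85, 0.88, 0.92]
        b = [0.84, 0.86, 0.83, 0.87]
        d = [ai - bi for ai, bi in zip(a, b)]
        mean = sum(d) / 4
        sd = math.sqrt(sum((x - mean) ** 2 for x in d) / 3)
        expected_t = mean / (sd / math.sqrt(4))
        t, p = ev.paired_t_test(a, b)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert 0 < p < 1


def fleiss_by_formula(counts):
    """Independent implementation from the published definition."""
    counts = np.asarray(counts, dtype=float)
    n_items, _ = counts.shape
    n = counts[0].sum()
    p_j = counts.sum(axis=0) / (n_items * n)
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_e = (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


class TestFleissKappa:
    def test_perfect_agreement(self):
        ratings = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
        assert ev.fleiss_kappa(ratings).kappa == pytest.approx(1.0)

    def test_matches_formula_on_worked_matrix(self):
        ratings = np.array([
            [0, 0, 3], [0, 3, 0], [1, 1, 1], [0, 1, 2],
            [2, 1, 0], [3, 0, 0], [1, 2, 0], [0, 0, 3],
        ])
        res = ev.fleiss_kappa(ratings)
        assert res.kappa == pytest.approx(fleiss_by_formula(ratings), abs=1e-12)
        assert res.n_raters == 3 and res.n_items == 8

    def test_ragged_matrix_is_error(self):
        with pytest.raises(ValueError, match="ragged"):
            ev.fleiss_kappa(np.array([[3, 0], [1, 1]]))

    def test_cohen_two_raters(self):
        res = ev.cohen_kappa(["A", "B", "A", "A"], ["A", "B", "A", "A"])
        assert res.kappa == pytest.approx(1.0)
        assert res.method == "cohen"


class TestLearningCurve:
    def test_full_size_equals_plain_cv(self):
        recs = _records(24, 26)
        table = ev.learning_curve([50], MajorityPipeline, recs, k=4, seed=3)
        plain = ev.kfold_cv(recs, MajorityPipeline, k=4, seed=3)
        assert table == [(50, plain.mean_accuracy)]

    def test_deterministic(self):
        recs = _records(30, 30)
        t1 = ev.learning_curve([20, 40], OraclePipeline, recs, k=4, seed=2)
        t2 = ev.learning_curve([20, 40], OraclePipeline, recs, k=4, seed=2)
        assert t1 == t2

    def test_oversized_request_is_error(self):
        with pytest.raises(ValueError):
            ev.learning_curve([100], MajorityPipeline, _records(10, 10), seed=0)
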