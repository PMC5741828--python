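"""Experimental protocol: splits, cross-validation, metrics and agreement.

The canonical protocol is stratified 4-fold cross-validation — each fold
holds out 25% of the data, which realizes the 75%-train / 25%-test design
— with accuracy, precision and recall (ADE is the positive class), ROC-AUC
from the tie-corrected rank statistic, paired t-tests to compare
classifiers fold-by-fold, learning curves over training-set size, and
chance-corrected annotator agreement (Fleiss' kappa for >= 2 raters,
Cohen's for pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .records import Label, SentenceRecord

#: A pipeline fits on training records and returns, for test records,
#: predicted labels plus real-valued scores (higher = more ADE-like).
PipelineFactory = Callable[[], "Pipeline"]


class Pipeline:
    """Contract for anything evaluated by :func:`kfold_cv`."""

    def fit(self, records: Sequence[SentenceRecord]) -> "Pipeline":
        raise NotImplementedError

    def predict(self, records: Sequence[SentenceRecord]) -> Tuple[List[Label], np.ndarray]:
        raise NotImplementedError


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float


@dataclass
class FoldResult:
    metrics: Metrics
    auc: float
    n_test: int


@dataclass
class CVResult:
    folds: List[FoldResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.metrics.accuracy for f in self.folds]))

    @property
    def std_accuracy(self) -> float:
        return float(np.std([f.metrics.accuracy for f in self.folds]))

    @property
    def mean_precision(self) -> float:
        return float(np.mean([f.metrics.precision for f in self.folds]))

    @property
    def mean_recall(self) -> float:
        return float(np.mean([f.metrics.recall for f in self.folds]))

    @property
    def fold_aucs(self) -> List[float]:
        return [f.auc for f in self.folds]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass
class KappaResult:
    kappa: float
    n_items: int
    n_raters: int
    method: str


def confusion(true: Sequence[Label], pred: Sequence[Label]) -> ConfusionCounts:
    c = ConfusionCounts()
    for t, p in zip(true, pred):
        if t is Label.ADE and p is Label.ADE:
            c.tp += 1
        elif t is Label.NO_ADE and p is Label.ADE:
            c.fp += 1
        elif t is Label.ADE and p is Label.NO_ADE:
            c.fn += 1
        else:
            c.tn += 1
    return c


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall with ADE as positive class.

    An empty positive prediction set gives precision 0 (convention), and
    an empty positive truth set gives recall 0.
    """
    if c.total == 0:
        raise ValueError("no evaluated sentences")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return Metrics(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
    )


def stratified_split(
    records: Sequence[SentenceRecord],
    train_frac: float = 0.75,
    seed: int = 0,
) -> Tuple[List[SentenceRecord], List[SentenceRecord]]:
    """Class-stratified train/test split, deterministic per seed.

    Per-class training counts are ``round(train_frac * n_class)``, so the
    class proportions are preserved within one record.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    labels = {rec.label for rec in records}
    if len(labels) < 2:
        raise ValueError("both classes must be present for a stratified split")
    rng = np.random.default_rng(seed)
    train: List[SentenceRecord] = []
    test: List[SentenceRecord] = []
    for label in sorted(labels, key=lambda l: l.value):
        group = [rec for rec in records if rec.label is label]
        order = rng.permutation(len(group))
        n_train = int(round(train_frac * len(group)))
        for rank, idx in enumerate(order):
            (train if rank < n_train else test).append(group[idx])
    return train, test


def kfold_cv(
    records: Sequence[SentenceRecord],
    pipeline_factory: PipelineFactory,
    k: int = 4,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of a pipeline.

    Folds are disjoint and cover the data; each fold's pipeline is a fresh
    instance fitted on the remaining k-1 folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    records = list(records)
    y = np.array([rec.label.value for rec in records])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(np.unique(y, return_inverse=True)[1])) < k:
        raise ValueError(
            f"a class has fewer than k={k} records; every fold needs both classes"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: List[FoldResult] = []
    for train_idx, test_idx in skf.split(np.zeros(len(records)), y):
        pipe = pipeline_factory().fit([records[i] for i in train_idx])
        test = [records[i] for i in test_idx]
        pred_labels, scores = pipe.predict(test)
        true = [rec.label for rec in test]
        metrics = compute_metrics(confusion(true, pred_labels))
        auc, _ = roc_auc(scores, [t is Label.ADE for t in true])
        folds.append(FoldResult(metrics=metrics, auc=auc, n_test=len(test)))
    return CVResult(folds=folds)


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool]
) -> Tuple[float, List[Tuple[float, float]]]:
    """AUC by the tie-corrected rank (Mann-Whitney) statistic plus curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half. The (fpr, tpr) curve comes from
    a threshold sweep.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test on matched measurements (e.g., per-fold AUCs).

    Degenerate cases are signaled rather than erroring: identical lists
    give ``(0.0, 1.0)``; a constant non-zero difference (zero variance)
    gives ``(±inf, 0.0)``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def fleiss_kappa(ratings: np.ndarray) -> KappaResult:
    """Fleiss' kappa from an items x categories count matrix.

    Every item must be rated by the same number of raters (equal row sums).
    """
    ratings = np.asarray(ratings, dtype=np.int64)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D items x categories count matrix")
    row_sums = ratings.sum(axis=1)
    if len(np.unique(row_sums)) != 1:
        raise ValueError("ragged ratings: all items need the same number of raters")
    n_raters = int(row_sums[0])
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    kappa = float(_sm_fleiss(ratings, method="fleiss"))
    return KappaResult(kappa=kappa, n_items=ratings.shape[0], n_raters=n_raters, method="fleiss")


def cohen_kappa(rater_a: Sequence, rater_b: Sequence) -> KappaResult:
    """Cohen's kappa for exactly two raters over categorical items."""
    if len(rater_a) != len(rater_b):
        raise ValueError("raters must label the same items")
    kappa = float(cohen_kappa_score(list(rater_a), list(rater_b)))
    return KappaResult(kappa=kappa, n_items=len(rater_a), n_raters=2, method="cohen")


def learning_curve(
    dataset_sizes: Sequence[int],
    pipeline_factory: PipelineFactory,
    records: Sequence[SentenceRecord],
    k: int = 4,
    seed: int = 0,
) -> List[Tuple[int, float]]:
    """Mean CV accuracy at increasing training-set sizes.

    For each size, a stratified subsample of that many records is drawn and
    cross-validated; deterministic per seed.
    """
    records = list(records)
    out: List[Tuple[int, float]] = []
    for n in dataset_sizes:
        if n > len(records):
            raise ValueError(f"requested size {n} exceeds corpus size {len(records)}")
        if n == len(records):
            subset = records
        else:
            subset, _ = stratified_split(records, train_frac=n / len(records), seed=seed)
            # rounding in the per-class quotas can leave a one-off count
            subset = subset[:n]
        result = kfold_cv(subset, pipeline_factory, k=k, seed=seed)
        out.append((n, result.mean_accuracy))
    return out
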