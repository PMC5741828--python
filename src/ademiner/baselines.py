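"""Bag-of-words baselines: n-gram/POS features with NB, SVM and trees.

The comparison arm for the embedding classifier. Sentences become sparse
count vectors over uni-grams, adjacent-token bi-grams and coarse POS-tag
counts (feature names are namespaced ``uni:``, ``bi:``, ``pos:``).
Multinomial naive Bayes is implemented natively (closed-form fit,
``argmax_c log P(c) + sum_f count_f * log P(f|c)`` with Laplace smoothing);
SVM and decision tree delegate to scikit-learn behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .records import SentenceRecord


@dataclass
class FeatureSpec:
    use_unigrams: bool = True
    use_bigrams: bool = True
    use_pos: bool = True
    min_df: int = 1

    def __post_init__(self) -> None:
        if not (self.use_unigrams or self.use_bigrams or self.use_pos):
            raise ValueError("at least one feature family must be enabled")
        if self.min_df < 1:
            raise ValueError("min_df must be >= 1")


@dataclass
class SparseFeatures:
    """Sentence-by-feature count matrix with a stable feature index."""

    matrix: sp.csr_matrix
    feature_index: Dict[str, int]
    spec: FeatureSpec

    @property
    def vocab_size(self) -> int:
        return len(self.feature_index)

    def feature_names(self) -> List[str]:
        names = [""] * len(self.feature_index)
        for name, j in self.feature_index.items():
            names[j] = name
        return names


def _sentence_features(rec: SentenceRecord, spec: FeatureSpec) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    if spec.use_unigrams:
        for tok in rec.tokens:
            key = "uni:" + tok
            counts[key] = counts.get(key, 0) + 1
    if spec.use_bigrams:
        for a, b in zip(rec.tokens, rec.tokens[1:]):
            key = f"bi:{a}_{b}"
            counts[key] = counts.get(key, 0) + 1
    if spec.use_pos:
        if rec.tokens and not rec.pos_tags:
            raise ValueError(
                f"{rec.sent_id}: use_pos requires pos_tags (run preprocess.pos_tag)"
            )
        for tag in rec.pos_tags:
            key = "pos:" + tag
            counts[key] = counts.get(key, 0) + 1
    return counts


def featurize(
    sentences: Sequence[SentenceRecord],
    spec: FeatureSpec = FeatureSpec(),
    feature_index: Optional[Dict[str, int]] = None,
) -> SparseFeatures:
    """Count features per sentence.

    When ``feature_index`` is given (e.g., from the training fold), columns
    are mapped through it and unseen features are dropped; otherwise the
    index is built from these sentences with document-frequency pruning at
    ``spec.min_df`` (feature names sorted for a deterministic layout).
    """
    per_sentence = [_sentence_features(rec, spec) for rec in sentences]
    if feature_index is None:
        df: Dict[str, int] = {}
        for counts in per_sentence:
            for name in counts:
                df[name] = df.get(name, 0) + 1
        names = sorted(name for name, d in df.items() if d >= spec.min_df)
        feature_index = {name: j for j, name in enumerate(names)}
    rows, cols, vals = [], [], []
    for i, counts in enumerate(per_sentence):
        for name, c in counts.items():
            j = feature_index.get(name)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(per_sentence), len(feature_index)),
        dtype=np.float64,
    )
    return SparseFeatures(matrix=matrix, feature_index=feature_index, spec=spec)


class MultinomialNB:
    """Native multinomial naive Bayes with Laplace smoothing.

    ``fit`` is closed form: class log priors from label frequencies and
    feature log likelihoods ``log((N_cf + alpha) / (N_c + alpha * |F|))``.
    Unseen features at predict time are simply absent columns (smoothed by
    construction), never an error.
    """

    def __init__(self, alpha: float = 1.0) -> None:
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.alpha = alpha
        self.classes_: Optional[np.ndarray] = None

    def fit(self, X: sp.spmatrix, y: Sequence) -> "MultinomialNB":
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        X = sp.csr_matrix(X)
        n_features = X.shape[1]
        self.feature_log_prob_ = np.empty((len(self.classes_), n_features))
        self.class_log_prior_ = np.empty(len(self.classes_))
        for i, c in enumerate(self.classes_):
            mask = y == c
            nc = X[mask].sum(axis=0).A1
            total = nc.sum()
            self.class_log_prior_[i] = np.log(mask.sum() / len(y))
            self.feature_log_prob_[i] = np.log(
                (nc + self.alpha) / (total + self.alpha * n_features)
            )
        return self

    def joint_log_likelihood(self, X: sp.spmatrix) -> np.ndarray:
        X = sp.csr_matrix(X)
        return X @ self.feature_log_prob_.T + self.class_log_prior_

    def predict(self, X: sp.spmatrix) -> np.ndarray:
        return self.classes_[np.argmax(self.joint_log_likelihood(X), axis=1)]

    def decision_scores(self, X: sp.spmatrix) -> np.ndarray:
        """Log-odds of the second class vs the first (binary only)."""
        jll = self.joint_log_likelihood(X)
        if jll.shape[1] != 2:
            raise ValueError("decision_scores is defined for binary problems")
        return jll[:, 1] - jll[:, 0]


def train_multinomial_nb(
    features: SparseFeatures, labels: Sequence, alpha: float = 1.0
) -> MultinomialNB:
    return MultinomialNB(alpha=alpha).fit(features.matrix, labels)


@dataclass
class ExternalModel:
    """scikit-learn classifier behind a uniform predict/scores contract."""

    kind: str
    estimator: object
    params: Dict = field(default_factory=dict)

    def predict(self, X: sp.spmatrix) -> np.ndarray:
        return self.estimator.predict(X)

    def decision_scores(self, X: sp.spmatrix) -> np.ndarray:
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(X))
        proba = self.estimator.predict_proba(X)
        return proba[:, 1] - proba[:, 0]


#: Best reported SVM settings from the study this tool reproduces: RBF
#: kernel, seed 1, no input normalization. The original "loss of 0.12"
#: setting came from a different toolkit and has no direct equivalent
#: here; it is carried verbatim (key ``loss``) without interpretation.
DEFAULT_SVM_PARAMS: Dict = {"kernel": "rbf", "random_state": 1, "loss": 0.12}


class _ConstantEstimator:
    """Degenerate fit on a single-class training set: always that label."""

    def __init__(self, label) -> None:
        self.label = label

    def predict(self, X) -> np.ndarray:
        return np.full(X.shape[0], self.label)

    def decision_function(self, X) -> np.ndarray:
        return np.zeros(X.shape[0])


def train_external(
    kind: str,
    features: SparseFeatures,
    labels: Sequence,
    params: Optional[Dict] = None,
) -> ExternalModel:
    """Fit an SVM (RBF kernel) or decision tree on the feature matrix."""
    params = dict(params or {})
    if kind not in ("svm", "decision_tree"):
        raise ValueError(f"unknown baseline kind: {kind!r}")
    unique = np.unique(np.asarray(labels))
    if len(unique) == 1:
        return ExternalModel(kind=kind, estimator=_ConstantEstimator(unique[0]), params=params)
    if kind == "svm":
        merged = {**DEFAULT_SVM_PARAMS, **params}
        merged.pop("loss", None)  # documented, uninterpreted legacy knob
        est = SVC(**merged)
    else:
        params.setdefault("random_state", 1)
        est = DecisionTreeClassifier(**params)
    est.fit(features.matrix, np.asarray(labels))
    return ExternalModel(kind=kind, estimator=est, params=params)
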