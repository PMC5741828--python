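"""Ready-made train/predict pipelines for cross-validation.

These adapt the embedding classifier and the bag-of-words baselines to the
:class:`ademiner.evaluation.Pipeline` contract (fit on records, predict
labels plus real-valued scores where higher means more ADE-like).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import baselines, nn_classifier
from .embedding import EmbeddingModel, Hyperparameters, train_skipgram
from .evaluation import Pipeline
from .records import Label, SentenceRecord


class PrototypePipeline(Pipeline):
    """Embed the training fold, fit class prototypes, score by cosine margin.

    The skip-gram model is trained on the training fold's token lists only
    (no test leakage); the score is ``cos(sentence, ADE prototype) -
    cos(sentence, No-ADE prototype)``.
    """

    def __init__(self, hyper: Optional[Hyperparameters] = None) -> None:
        self.hyper = hyper or Hyperparameters()
        self.model: Optional[EmbeddingModel] = None
        self.prototypes = None

    def fit(self, records: Sequence[SentenceRecord]) -> "PrototypePipeline":
        corpus = [rec.tokens for rec in records]
        self.model = train_skipgram(corpus, self.hyper)
        self.prototypes = nn_classifier.fit_prototypes(self.model, records)
        return self

    def predict(
        self, records: Sequence[SentenceRecord]
    ) -> Tuple[List[Label], np.ndarray]:
        preds = nn_classifier.classify_many(self.model, self.prototypes, records)
        labels = [p.label for p in preds]
        scores = np.array([p.score_ade - p.score_noade for p in preds])
        return labels, scores


class BowPipeline(Pipeline):
    """Bag-of-words features + one of {nb, svm, decision_tree}."""

    def __init__(
        self,
        classifier: str = "nb",
        spec: Optional[baselines.FeatureSpec] = None,
        alpha: float = 1.0,
        params: Optional[Dict] = None,
    ) -> None:
        if classifier not in ("nb", "svm", "decision_tree"):
            raise ValueError(f"unknown classifier: {classifier!r}")
        self.classifier = classifier
        self.spec = spec or baselines.FeatureSpec()
        self.alpha = alpha
        self.params = params
        self.feature_index = None
        self.model = None

    def fit(self, records: Sequence[SentenceRecord]) -> "BowPipeline":
        feats = baselines.featurize(records, self.spec)
        self.feature_index = feats.feature_index
        y = [rec.label.value for rec in records]
        if self.classifier == "nb":
            self.model = baselines.train_multinomial_nb(feats, y, alpha=self.alpha)
        else:
            self.model = baselines.train_external(self.classifier, feats, y, self.params)
        return self

    def predict(
        self, records: Sequence[SentenceRecord]
    ) -> Tuple[List[Label], np.ndarray]:
        feats = baselines.featurize(records, self.spec, feature_index=self.feature_index)
        raw = self.model.predict(feats.matrix)
        labels = [Label(v) for v in raw]
        scores = self.model.decision_scores(feats.matrix)
        # decision_scores orders classes alphabetically: ADE < NO_ADE, so the
        # second-vs-first log-odds favors NO_ADE; flip so higher = more ADE.
        return labels, -np.asarray(scores, dtype=np.float64)
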