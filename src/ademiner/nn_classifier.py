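"""Cosine-prototype sentence classification and self-training.

A sentence is embedded as the unweighted mean of its in-vocabulary word
vectors. Each class (ADE, No-ADE) gets a prototype: the mean of its
training-sentence vectors. A new sentence is assigned the class whose
prototype has the highest cosine similarity to the sentence vector; ties
and unembeddable (all-OOV) sentences fall back to No-ADE, a deliberately
precision-first default for a signal-detection tool.

Self-training grows the labeled pool: confidently classified unlabeled
sentences (cosine margin above a threshold) re-enter training as
machine-labeled records, mirroring the construction of augmented training
sets from an initial human-labeled seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

from .embedding import EmbeddingModel, cosine_similarity, word_vector
from .records import Label, LabelSource, SentenceRecord

#: Sentence composition hook: maps per-token vectors to one sentence vector.
Composer = Callable[[np.ndarray], np.ndarray]


@dataclass
class ClassPrototype:
    label: Label
    vector: np.ndarray
    n_support: int

    def __post_init__(self) -> None:
        if self.n_support < 1:
            raise ValueError("prototype needs at least one supporting sentence")
        if not np.all(np.isfinite(self.vector)) or not np.any(self.vector):
            raise ValueError("prototype vector must be finite and non-zero")


@dataclass
class Prediction:
    label: Label
    score_ade: float
    score_noade: float

    @property
    def margin(self) -> float:
        return abs(self.score_ade - self.score_noade)


def sentence_vector(
    model: EmbeddingModel,
    tokens: Sequence[str],
    composer: Optional[Composer] = None,
) -> Optional[np.ndarray]:
    """Mean of in-vocabulary word vectors; ``None`` if every token is OOV.

    ``composer`` replaces the unweighted mean (rows = token vectors) for
    experiments with weighted composition.
    """
    rows = [vec for tok in tokens if (vec := word_vector(model, tok)) is not None]
    if not rows:
        return None
    stacked = np.stack(rows).astype(np.float64)
    if composer is not None:
        return np.asarray(composer(stacked), dtype=np.float64)
    return stacked.mean(axis=0)


def fit_prototypes(
    model: EmbeddingModel,
    labeled: Sequence[SentenceRecord],
    composer: Optional[Composer] = None,
) -> List[ClassPrototype]:
    """One prototype per class = mean of that class's sentence vectors.

    All-OOV sentences are skipped (they carry no embedding signal); a class
    with zero usable sentences is an error.
    """
    sums = {Label.ADE: None, Label.NO_ADE: None}
    ns = {Label.ADE: 0, Label.NO_ADE: 0}
    for rec in labeled:
        if rec.label not in sums:
            continue
        vec = sentence_vector(model, rec.tokens, composer)
        if vec is None:
            continue
        sums[rec.label] = vec if sums[rec.label] is None else sums[rec.label] + vec
        ns[rec.label] += 1
    protos: List[ClassPrototype] = []
    for label in (Label.ADE, Label.NO_ADE):
        if ns[label] == 0:
            raise ValueError(f"no usable training sentences for class {label.value}")
        protos.append(ClassPrototype(label, sums[label] / ns[label], ns[label]))
    return protos


def _proto_map(prototypes: Sequence[ClassPrototype]):
    m = {p.label: p for p in prototypes}
    if set(m) != {Label.ADE, Label.NO_ADE}:
        raise ValueError("need exactly one prototype per class (ADE, NO_ADE)")
    return m


def classify(
    model: EmbeddingModel,
    prototypes: Sequence[ClassPrototype],
    sentence: SentenceRecord,
    composer: Optional[Composer] = None,
) -> Prediction:
    """Assign the class whose prototype is most cosine-similar.

    Exact ties and all-OOV sentences default to No-ADE with margin 0.
    """
    protos = _proto_map(prototypes)
    vec = sentence_vector(model, sentence.tokens, composer)
    if vec is None:
        return Prediction(Label.NO_ADE, 0.0, 0.0)
    s_ade = cosine_similarity(vec, protos[Label.ADE].vector)
    s_no = cosine_similarity(vec, protos[Label.NO_ADE].vector)
    label = Label.ADE if s_ade > s_no else Label.NO_ADE
    return Prediction(label, s_ade, s_no)


def classify_many(
    model: EmbeddingModel,
    prototypes: Sequence[ClassPrototype],
    sentences: Sequence[SentenceRecord],
    composer: Optional[Composer] = None,
) -> List[Prediction]:
    return [classify(model, prototypes, s, composer) for s in sentences]


def self_train(
    model: EmbeddingModel,
    prototypes: Sequence[ClassPrototype],
    unlabeled: Sequence[SentenceRecord],
    confidence_threshold: float = 0.2,
    max_added: Optional[int] = None,
) -> List[SentenceRecord]:
    """Machine-label confidently classified sentences.

    Returns copies of the input records with the predicted label and
    ``label_source=machine``, keeping only predictions whose cosine margin
    is at least ``confidence_threshold``, ordered by margin descending
    (ties by sent_id) and capped at ``max_added``.
    """
    if not (0 <= confidence_threshold < 1):
        raise ValueError("confidence_threshold must lie in [0, 1)")
    if max_added is not None and max_added < 0:
        raise ValueError("max_added must be >= 0")
    scored = []
    for rec in unlabeled:
        pred = classify(model, prototypes, rec)
        if sentence_vector(model, rec.tokens) is None:
            continue  # no evidence, never pseudo-label
        if pred.margin >= confidence_threshold:
            scored.append((pred.margin, rec.sent_id, rec, pred.label))
    scored.sort(key=lambda t: (-t[0], t[1]))
    if max_added is not None:
        scored = scored[:max_added]
    return [
        replace(rec, label=label, label_source=LabelSource.MACHINE)
        for _, _, rec, label in scored
    ]
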