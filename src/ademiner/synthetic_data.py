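"""Synthetic corpora with the statistical structure the pipeline assumes.

Real pharmacovigilance corpora (tens of millions of article and blog
sentences) cannot ship with a desk-scale toolkit, so tests and examples
run on generated data that emulates the structure the classifier exploits:

* two sentence classes (ADE / No-ADE) whose distinction is carried by
  class-specific context words, NOT by lexicon presence — No-ADE sentences
  also co-mention drugs and events (a drug and an event in one sentence do
  not imply causation: indications, negations, incidental mentions);
* drug and adverse-event terms drawn from the shipped lexicons;
* a shared Zipf-weighted background vocabulary;
* label noise (annotator error) and class imbalance.

Class sizes are quota-based (exact counts), so tests have exact
expectations; everything is deterministic per seed (PCG64 integer-state
generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .ade_stats import DrugEventPair, extract_pairs
from .corpus_io import default_drug_lexicon, default_event_lexicon
from .preprocess import tokenize
from .records import Label, LabelSource, Lexicon, SentenceRecord


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic corpus.

    Defaults mirror the study conditions this toolkit is exercised under:
    8,000 sentences at ADE fraction 0.48 (the class balance of the largest
    combined annotation set, 10,548 ADE of 21,843) with 2% label noise.
    ``signal_rate`` is the per-slot probability that a class-signal word
    (rather than a background word) fills a free token slot.
    """

    n_sentences: int = 8000
    ade_fraction: float = 0.48
    sentence_length: Tuple[int, int] = (5, 9)
    n_background_words: int = 150
    n_ade_signal_words: int = 15
    n_noade_signal_words: int = 15
    signal_rate: float = 0.7
    drug_comention_rate: float = 0.8
    event_comention_rate: float = 0.8
    drugs: Optional[Lexicon] = None
    events: Optional[Lexicon] = None
    label_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ade_fraction", "signal_rate", "label_noise",
                     "drug_comention_rate", "event_comention_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sentence_length[0] < 3 or self.sentence_length[1] < self.sentence_length[0]:
            raise ValueError("sentence_length must satisfy 3 <= min <= max")
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be positive")


@dataclass
class GoldCorpus:
    sentences: List[SentenceRecord]
    gold_pairs: List[DrugEventPair]
    config: GeneratorConfig


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_corpus(config: GeneratorConfig = GeneratorConfig()) -> GoldCorpus:
    """Generate a labeled corpus of ADE and No-ADE sentences.

    ADE sentences always contain one drug term, one event term and
    class-signal words at ``signal_rate``; No-ADE sentences contain drug
    and/or event terms (co-mention without causation) plus their own
    signal words. Gold labels are flipped with probability ``label_noise``
    after construction; ``gold_pairs`` are recomputed from the final
    ADE-labeled sentences so the corpus is self-consistent under
    :func:`ademiner.ade_stats.extract_pairs`.
    """
    drugs = config.drugs or default_drug_lexicon()
    events = config.events or default_event_lexicon()
    rng = np.random.default_rng(config.seed)

    drug_terms = drugs.sorted_terms()
    event_terms = events.sorted_terms()
    background = [f"bg{i:03d}" for i in range(config.n_background_words)]
    bg_weights = _zipf_weights(config.n_background_words)
    ade_signal = [f"adecue{i:02d}" for i in range(config.n_ade_signal_words)]
    noade_signal = [f"benigncue{i:02d}" for i in range(config.n_noade_signal_words)]

    n_ade = int(round(config.n_sentences * config.ade_fraction))
    is_ade = np.zeros(config.n_sentences, dtype=bool)
    is_ade[:n_ade] = True
    is_ade = is_ade[rng.permutation(config.n_sentences)]

    lo, hi = config.sentence_length
    records: List[SentenceRecord] = []
    for i in range(config.n_sentences):
        length = int(rng.integers(lo, hi + 1))
        units: List[List[str]] = []
        if is_ade[i]:
            units.append([drug_terms[rng.integers(len(drug_terms))]])
            units.append(tokenize(event_terms[rng.integers(len(event_terms))]))
            signal_words = ade_signal
        else:
            if rng.random() < config.drug_comention_rate:
                units.append([drug_terms[rng.integers(len(drug_terms))]])
            if rng.random() < config.event_comention_rate:
                units.append(tokenize(event_terms[rng.integers(len(event_terms))]))
            signal_words = noade_signal
        n_slots = max(1, length - len(units))
        for _ in range(n_slots):
            if signal_words and rng.random() < config.signal_rate:
                units.append([signal_words[rng.integers(len(signal_words))]])
            else:
                units.append([background[rng.choice(len(background), p=bg_weights)]])
        order = rng.permutation(len(units))
        tokens = [tok for j in order for tok in units[j]]
        gold = Label.ADE if is_ade[i] else Label.NO_ADE
        if config.label_noise > 0 and rng.random() < config.label_noise:
            gold = Label.NO_ADE if gold is Label.ADE else Label.ADE
        text = " ".join(tokens)
        records.append(
            SentenceRecord(
                sent_id=f"syn{i:06d}",
                doc_id="synthetic",
                text_raw=text,
                text_norm=text,
                tokens=tokens,
                label=gold,
                label_source=LabelSource.HUMAN,
            )
        )

    ade_sentences = [r for r in records if r.label is Label.ADE]
    gold_pairs = extract_pairs(ade_sentences, drugs, events)
    return GoldCorpus(sentences=records, gold_pairs=gold_pairs, config=config)


def hide_labels(records: Sequence[SentenceRecord]) -> List[SentenceRecord]:
    """Strip labels (for self-training pools), keeping gold elsewhere."""
    return [
        replace(r, label=Label.UNLABELED, label_source=LabelSource.NONE)
        for r in records
    ]


def generate_planted_topic_corpus(
    n_sentences: int,
    n_topics: int = 2,
    vocab_per_topic: int = 50,
    seed: int = 0,
    sentence_length: Tuple[int, int] = (5, 9),
) -> List[List[str]]:
    """Token lists where each sentence draws from exactly one topic's vocabulary.

    Topics share no words, so within-topic pairs co-occur and between-topic
    pairs never do — the cleanest possible testbed for embedding trainers.
    """
    if n_topics < 2:
        raise ValueError("need at least 2 topics")
    rng = np.random.default_rng(seed)
    vocabs = [
        [f"t{k}w{j:03d}" for j in range(vocab_per_topic)] for k in range(n_topics)
    ]
    lo, hi = sentence_length
    corpus: List[List[str]] = []
    for i in range(n_sentences):
        topic = int(rng.integers(n_topics))
        length = int(rng.integers(lo, hi + 1))
        corpus.append(
            [vocabs[topic][int(rng.integers(vocab_per_topic))] for _ in range(length)]
        )
    return corpus


def generate_ratings(
    n_items: int,
    n_raters: int = 3,
    n_categories: int = 3,
    agreement: float = 0.84,
    seed: int = 0,
) -> np.ndarray:
    """Items x categories count matrix for agreement statistics.

    Per item: with probability ``agreement`` all raters copy a latent
    uniform label; otherwise each rater votes uniformly at random.
    """
    if not (0 <= agreement <= 1):
        raise ValueError("agreement must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_items, n_categories), dtype=np.int64)
    for i in range(n_items):
        latent = int(rng.integers(n_categories))
        if rng.random() < agreement:
            out[i, latent] = n_raters
        else:
            for _ in range(n_raters):
                out[i, int(rng.integers(n_categories))] += 1
    return out
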