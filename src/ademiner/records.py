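"""Core record types shared across the pipeline.

A :class:`SentenceRecord` is the atom of the whole toolkit: every stage
(normalization, candidate filtering, embedding, classification, statistics)
consumes or produces lists of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Set


class Label(str, Enum):
    """Sentence-level annotation: does the sentence assert a drug-event harm?"""

    ADE = "ADE"
    NO_ADE = "NO_ADE"
    NOT_DECIDED = "NOT_DECIDED"
    UNLABELED = "UNLABELED"


class LabelSource(str, Enum):
    HUMAN = "human"
    MACHINE = "machine"
    NONE = "none"


class DocSource(str, Enum):
    BIOMEDICAL_ARTICLE = "biomedical_article"
    SOCIAL_MEDIA = "social_media"


@dataclass
class DocumentRecord:
    """A raw document (article or blog post) with free-form metadata."""

    doc_id: str
    source: DocSource
    text: str
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass
class SentenceRecord:
    """A normalized, tokenized sentence with label and provenance.

    Invariants enforced by :meth:`validate`:

    * ``pos_tags`` is either empty or aligned one-to-one with ``tokens``;
    * ``label_source == NONE`` exactly when ``label == UNLABELED``.
    """

    sent_id: str
    doc_id: str
    text_raw: str
    text_norm: str
    tokens: List[str]
    pos_tags: List[str] = field(default_factory=list)
    label: Label = Label.UNLABELED
    label_source: LabelSource = LabelSource.NONE

    def validate(self) -> "SentenceRecord":
        if not self.sent_id:
            raise ValueError("sent_id must be non-empty")
        if self.pos_tags and len(self.pos_tags) != len(self.tokens):
            raise ValueError(
                f"{self.sent_id}: pos_tags length {len(self.pos_tags)} "
                f"!= tokens length {len(self.tokens)}"
            )
        if (self.label_source is LabelSource.NONE) != (self.label is Label.UNLABELED):
            raise ValueError(
                f"{self.sent_id}: label_source=none must coincide with "
                f"label=UNLABELED (got {self.label.value}/{self.label_source.value})"
            )
        return self


@dataclass
class Lexicon:
    """A named set of lower-cased (possibly multi-word) terms.

    Terms are stored exactly as the sentence normalizer would produce them,
    so token-boundary matching against normalized sentences is well defined.
    """

    name: str
    terms: Set[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"lexicon {self.name!r} is empty")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def sorted_terms(self) -> List[str]:
        return sorted(self.terms)
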