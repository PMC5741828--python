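"""Text normalization, segmentation, tokenization, tagging and filtering.

This stage turns raw documents into candidate sentences for ADE
classification:

1. :func:`normalize_text` — lower-case, ASCII-transliterate, delete
   configured punctuation patterns, collapse whitespace;
2. :func:`split_sentences` — abbreviation-aware sentence segmentation;
3. :func:`tokenize` — deterministic alphanumeric tokenization
   (hyphenated words split);
4. :func:`pos_tag` — a small deterministic rule-based coarse tagger;
5. :func:`filter_candidates` — keep only sentences mentioning at least one
   drug term AND one adverse-event term (token-boundary match);
6. :func:`exclude_not_decided` — drop sentences annotators could not decide,
   leaving the binary ADE / No-ADE problem.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .records import Label, Lexicon, SentenceRecord

#: Default deletion patterns: square/round brackets, question/exclamation
#: marks and straight/typographic quotes. Applied in order; configurable.
DEFAULT_DELETE_PATTERNS: Tuple[str, ...] = (
    r"\[", r"\]", r"\(", r"\)", r"\?", r"!", r'"', r"'", "“", "”",
    "‘", "’",
)


@dataclass
class NormalizationConfig:
    lowercase: bool = True
    ascii_transliterate: bool = True
    delete_patterns: Tuple[str, ...] = DEFAULT_DELETE_PATTERNS


def normalize_text(text: str, config: NormalizationConfig = NormalizationConfig()) -> str:
    """Normalize raw text to a canonical lower-case ASCII form.

    Idempotent: applying it twice gives the same string. ASCII
    transliteration is NFKD decomposition with combining marks (and any
    remaining non-ASCII characters) dropped, not replaced.
    """
    out = text
    if config.lowercase:
        out = out.lower()
    if config.ascii_transliterate:
        out = unicodedata.normalize("NFKD", out)
        out = out.encode("ascii", "ignore").decode("ascii")
    for pat in config.delete_patterns:
        out = re.sub(pat, "", out)
    out = re.sub(r"\s+", " ", out).strip()
    return out


# Common abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS: Set[str] = {
    "e.g", "i.e", "eg", "ie", "etc", "vs", "cf", "al", "fig", "figs",
    "dr", "mr", "mrs", "ms", "prof", "st", "no", "ca", "approx",
}

_SENT_END = re.compile(r"[.!?]+")


def split_sentences(text: str) -> List[str]:
    """Split text into sentences at ``. ! ?`` boundaries, best-effort.

    Guards against splitting inside decimal numbers (``3.5``) and after
    common abbreviations (``e.g.``, ``et al.``). Preserves every
    non-whitespace character of the input across the returned segments.
    """
    if not text.strip():
        return []
    sentences: List[str] = []
    start = 0
    for m in _SENT_END.finditer(text):
        end = m.end()
        # decimal number: digit on both sides of a single period
        if (
            m.group() == "."
            and m.start() > 0
            and text[m.start() - 1].isdigit()
            and end < len(text)
            and text[end].isdigit()
        ):
            continue
        # abbreviation guard: look at the word immediately before the period
        prev = re.search(r"([A-Za-z][A-Za-z.]*)$", text[: m.start()])
        if m.group() == "." and prev and prev.group(1).lower().rstrip(".") in _ABBREVIATIONS:
            continue
        # single-letter word: an initial ("J. Smith") or the head of a
        # letter-dotted abbreviation ("e.g.")
        if m.group() == "." and prev and len(prev.group(1)) == 1:
            continue
        segment = text[start:end].strip()
        if segment:
            sentences.append(segment)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


_TOKEN = re.compile(r"[A-Za-z0-9]+")


def tokenize(sentence: str) -> List[str]:
    """Alphanumeric tokenization; punctuation and hyphens split tokens."""
    return _TOKEN.findall(sentence)


# ---------------------------------------------------------------------------
# Coarse POS tagging
#
# A deterministic rule-based tagger over the tagset
# {NOUN, VERB, ADJ, ADV, PRON, DET, ADP, CONJ, NUM, PART, X}: closed-class
# lexicon first, then suffix heuristics, default NOUN. Coarse tags are all
# the downstream bag-of-words featurizer needs; the tagger is frozen so
# feature extraction is reproducible across machines.
# ---------------------------------------------------------------------------

POS_TAGSET = ("NOUN", "VERB", "ADJ", "ADV", "PRON", "DET", "ADP", "CONJ", "NUM", "PART", "X")

_CLOSED_CLASS: Dict[str, str] = {}
for _w in ("the", "a", "an", "this", "that", "these", "those", "some", "any", "each", "every", "no"):
    _CLOSED_CLASS[_w] = "DET"
for _w in ("i", "you", "he", "she", "it", "we", "they", "me", "him", "her",
           "us", "them", "my", "your", "his", "its", "our", "their", "who", "which", "what"):
    _CLOSED_CLASS[_w] = "PRON"
for _w in ("in", "on", "at", "by", "for", "with", "from", "to", "of", "into",
           "onto", "over", "under", "after", "before", "during", "without",
           "between", "among", "through", "about", "against"):
    _CLOSED_CLASS[_w] = "ADP"
for _w in ("and", "or", "but", "nor", "so", "yet", "because", "although",
           "while", "if", "when", "than", "whether"):
    _CLOSED_CLASS[_w] = "CONJ"
for _w in ("not", "n't"):
    _CLOSED_CLASS[_w] = "PART"
for _w in ("is", "are", "was", "were", "be", "been", "being", "am", "has",
           "have", "had", "do", "does", "did", "can", "could", "may", "might",
           "must", "shall", "should", "will", "would", "causes", "cause",
           "caused", "causing", "induces", "induce", "induced", "inducing",
           "reported", "reports", "showed", "shows", "developed", "develops",
           "experienced", "experiences", "occurred", "occurs", "associated",
           "received", "treated", "led", "leads", "resulted", "results"):
    _CLOSED_CLASS[_w] = "VERB"
for _w in ("very", "also", "however", "often", "usually", "rarely",
           "significantly", "severely", "mildly", "commonly", "frequently",
           "only", "most", "more", "less", "well", "then", "here", "there"):
    _CLOSED_CLASS[_w] = "ADV"

_SUFFIX_RULES: Tuple[Tuple[str, str], ...] = (
    ("ing", "VERB"), ("ized", "VERB"), ("ised", "VERB"),
    ("ly", "ADV"),
    ("ous", "ADJ"), ("ive", "ADJ"), ("ic", "ADJ"), ("al", "ADJ"),
    ("able", "ADJ"), ("ible", "ADJ"), ("ful", "ADJ"), ("less", "ADJ"),
    ("tion", "NOUN"), ("sion", "NOUN"), ("ment", "NOUN"), ("ness", "NOUN"),
    ("ity", "NOUN"), ("emia", "NOUN"), ("itis", "NOUN"), ("osis", "NOUN"),
    ("pathy", "NOUN"), ("algia", "NOUN"),
)


def pos_tag(tokens: Sequence[str]) -> List[str]:
    """Assign one coarse POS tag per token (see :data:`POS_TAGSET`).

    Deterministic: closed-class lookup, then numeric check, then suffix
    heuristics, defaulting to NOUN (the prior for biomedical text).
    """
    tags: List[str] = []
    for tok in tokens:
        low = tok.lower()
        if low in _CLOSED_CLASS:
            tags.append(_CLOSED_CLASS[low])
            continue
        if low.isdigit() or re.fullmatch(r"\d+(\.\d+)?", low):
            tags.append("NUM")
            continue
        if not any(c.isalpha() for c in low):
            tags.append("X")
            continue
        for suffix, tag in _SUFFIX_RULES:
            if len(low) > len(suffix) + 2 and low.endswith(suffix):
                tags.append(tag)
                break
        else:
            tags.append("NOUN")
    return tags


# ---------------------------------------------------------------------------
# Lexicon matching (token-boundary, longest-match for multi-word terms)
# ---------------------------------------------------------------------------

def _term_tuples(lexicon: Lexicon) -> Dict[str, List[Tuple[str, ...]]]:
    """Index lexicon terms by first token, longest terms first."""
    index: Dict[str, List[Tuple[str, ...]]] = {}
    for term in lexicon.sorted_terms():
        parts = tuple(tokenize(term))
        if not parts:
            continue
        index.setdefault(parts[0], []).append(parts)
    for cands in index.values():
        cands.sort(key=lambda t: (-len(t), t))
    return index


def match_terms(tokens: Sequence[str], lexicon: Lexicon) -> Set[str]:
    """Return lexicon terms present in a token sequence.

    Multi-word terms match as contiguous token runs; overlapping candidates
    resolve by longest match (the matched run is consumed before scanning
    continues).
    """
    index = _term_tuples(lexicon)
    found: Set[str] = set()
    i = 0
    n = len(tokens)
    while i < n:
        matched_len = 1
        for cand in index.get(tokens[i], ()):
            if tuple(tokens[i : i + len(cand)]) == cand:
                found.add(" ".join(cand))
                matched_len = len(cand)
                break
        i += matched_len
    return found


def filter_candidates(
    sentences: Sequence[SentenceRecord], drugs: Lexicon, events: Lexicon
) -> Tuple[List[SentenceRecord], int]:
    """Keep sentences containing at least one drug AND one event term.

    Sentences missing either side cannot express a drug-event interaction
    and are excluded before annotation/classification. Order is preserved;
    returns ``(kept, dropped_count)``.
    """
    kept: List[SentenceRecord] = []
    dropped = 0
    for rec in sentences:
        if match_terms(rec.tokens, drugs) and match_terms(rec.tokens, events):
            kept.append(rec)
        else:
            dropped += 1
    return kept, dropped


def exclude_not_decided(sentences: Sequence[SentenceRecord]) -> List[SentenceRecord]:
    """Drop NOT_DECIDED records, leaving the binary ADE / No-ADE problem."""
    return [rec for rec in sentences if rec.label is not Label.NOT_DECIDED]


def sentences_from_text(
    text: str,
    doc_id: str,
    config: NormalizationConfig = NormalizationConfig(),
    tag_pos: bool = False,
    id_prefix: str = "",
) -> List[SentenceRecord]:
    """Full Tier-2 path for one document: normalize, split, tokenize, tag."""
    records: List[SentenceRecord] = []
    for i, raw in enumerate(split_sentences(text)):
        norm = normalize_text(raw, config)
        tokens = tokenize(norm)
        if not tokens:
            continue
        records.append(
            SentenceRecord(
                sent_id=f"{id_prefix}{doc_id}:{i:04d}",
                doc_id=doc_id,
                text_raw=raw,
                text_norm=norm,
                tokens=tokens,
                pos_tags=pos_tag(tokens) if tag_pos else [],
            )
        )
    return records
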