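"""Reading and writing documents, sentences and lexicons.

All file handling lives here; computation modules never touch disk. On-disk
formats are line-oriented and diff-able: JSONL (UTF-8, one object per line)
for documents and sentences, plain text one-term-per-line for lexicons, and
a deliberately minimal PMC/JATS-style XML reader (article title + paragraph
text) for article dumps.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Union
from xml.etree import ElementTree

from .records import DocSource, DocumentRecord, Label, LabelSource, Lexicon, SentenceRecord

PathLike = Union[str, Path]

_DOC_REQUIRED = ("doc_id", "source", "text")


def read_documents(path: PathLike, format: str = "jsonl") -> List[DocumentRecord]:
    """Read a document collection.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"jsonl"`` (one JSON object per line with keys ``doc_id``,
        ``source``, ``text`` and optional ``meta``) or ``"pmc_xml"`` (a
        minimal JATS-style article: ``<article-title>`` plus ``<p>`` body
        paragraphs, concatenated in document order).
    """
    path = Path(path)
    if format == "jsonl":
        return _read_documents_jsonl(path)
    if format == "pmc_xml":
        return [_read_document_pmc_xml(path)]
    raise ValueError(f"unknown document format: {format!r}")


def _read_documents_jsonl(path: Path) -> List[DocumentRecord]:
    docs: List[DocumentRecord] = []
    seen = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from exc
            for key in _DOC_REQUIRED:
                if key not in obj:
                    raise ValueError(f"{path}:{lineno}: missing required field {key!r}")
            if obj["doc_id"] in seen:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {obj['doc_id']!r}")
            seen.add(obj["doc_id"])
            docs.append(
                DocumentRecord(
                    doc_id=obj["doc_id"],
                    source=DocSource(obj["source"]),
                    text=obj["text"],
                    meta=dict(obj.get("meta", {})),
                )
            )
    return docs


def _read_document_pmc_xml(path: Path) -> DocumentRecord:
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise ValueError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    parts: List[str] = []
    title = root.find(".//article-title")
    if title is not None:
        parts.append("".join(title.itertext()).strip())
    for p in root.iter("p"):
        text = "".join(p.itertext()).strip()
        if text:
            parts.append(text)
    meta = {}
    journal = root.find(".//journal-title")
    if journal is not None:
        meta["journal"] = "".join(journal.itertext()).strip()
    return DocumentRecord(
        doc_id=path.stem,
        source=DocSource.BIOMEDICAL_ARTICLE,
        text=" ".join(parts),
        meta=meta,
    )


def write_documents(docs: Iterable[DocumentRecord], path: PathLike) -> int:
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "source": doc.source.value,
                        "text": doc.text,
                        "meta": doc.meta,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


def write_sentences(records: Iterable[SentenceRecord], path: PathLike) -> int:
    """Write sentences as JSONL; loss-less round trip with :func:`read_sentences`."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            rec.validate()
            fh.write(
                json.dumps(
                    {
                        "sent_id": rec.sent_id,
                        "doc_id": rec.doc_id,
                        "text_raw": rec.text_raw,
                        "text_norm": rec.text_norm,
                        "tokens": rec.tokens,
                        "pos_tags": rec.pos_tags,
                        "label": rec.label.value,
                        "label_source": rec.label_source.value,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


def read_sentences(path: PathLike) -> List[SentenceRecord]:
    path = Path(path)
    out: List[SentenceRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from exc
            try:
                rec = SentenceRecord(
                    sent_id=obj["sent_id"],
                    doc_id=obj["doc_id"],
                    text_raw=obj["text_raw"],
                    text_norm=obj["text_norm"],
                    tokens=list(obj["tokens"]),
                    pos_tags=list(obj.get("pos_tags", [])),
                    label=Label(obj.get("label", "UNLABELED")),
                    label_source=LabelSource(obj.get("label_source", "none")),
                ).validate()
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing field {exc.args[0]!r}") from exc
            out.append(rec)
    return out


def load_lexicon(
    path: PathLike,
    normalizer: Optional[Callable[[str], str]] = None,
    name: Optional[str] = None,
) -> Lexicon:
    """Load a one-term-per-line lexicon; ``#`` starts a comment line.

    Every term passes through ``normalizer`` (defaults to lower-casing) so
    that lexicon terms live in the same normalized space as sentence text;
    duplicates after normalization collapse.
    """
    path = Path(path)
    norm = normalizer if normalizer is not None else str.lower
    terms = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term = norm(line)
            if term:
                terms.add(term)
    if not terms:
        raise ValueError(f"{path}: lexicon is empty after filtering")
    return Lexicon(name=name or path.stem, terms=terms)


def write_lexicon(lexicon: Lexicon, path: PathLike) -> int:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for term in lexicon.sorted_terms():
            fh.write(term + "\n")
    return len(lexicon)


def _data_path(fname: str) -> Path:
    return Path(__file__).parent / "data" / fname


def default_drug_lexicon() -> Lexicon:
    """The 28-drug list used for the drug-event visualization statistics."""
    return load_lexicon(_data_path("drugs_28.txt"), name="drugs")


def default_event_lexicon() -> Lexicon:
    """A small curated adverse-event term list shipped as a fixture."""
    return load_lexicon(_data_path("events_default.txt"), name="events")
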