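import pytest

from ademiner.records import Label, LabelSource, Lexicon, SentenceRecord
from ademiner.synthetic_data import GeneratorConfig, generate_corpus


def make_sentence(
    sent_id: str,
    tokens,
    label: Label = Label.UNLABELED,
    pos_tags=None,
) -> SentenceRecord:
    text = " ".join(tokens)
    source = LabelSource.NONE if label is Label.UNLABELED else LabelSource.HUMAN
    return SentenceRecord(
        sent_id=sent_id,
        doc_id="doc",
        text_raw=text,
        text_norm=text,
        tokens=list(tokens),
        pos_tags=list(pos_tags or []),
        label=label,
        label_source=source,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A small labeled corpus for fast classifier/evaluation tests."""
    return generate_corpus(
        GeneratorConfig(n_sentences=600, label_noise=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_lexicons():
    drugs = Lexicon("drugs", {"aspirin", "metformin", "warfarin"})
    events = Lexicon("events", {"bleeding", "nausea", "stomach pain"})
    return drugs, events
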