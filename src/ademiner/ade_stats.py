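"""Drug-event statistics over classified ADE sentences.

After classification, every ADE-labeled sentence that mentions drug and
adverse-event terms contributes within-sentence (drug, event) pairs. From
pair counts and per-drug sentence counts this module estimates the
conditional probability Pr(event | drug) = count / n_drug_sentences with
binomial confidence intervals (Wald with z at the chosen level, or
Wilson), and emits the co-occurrence matrices and per-drug frequency
tables behind the visualizations (word-cloud rendering is left to
external tools).

Matching is deterministic lexicon lookup on token boundaries (longest
match for multi-word terms); within one sentence a (drug, event) pair
counts once — presence, not frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .preprocess import match_terms
from .records import Lexicon, SentenceRecord


@dataclass(frozen=True)
class DrugEventPair:
    drug: str
    event: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("pair count must be >= 1")


@dataclass
class ProportionEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1):
            raise ValueError("CI must bracket p_hat within [0, 1]")


@dataclass
class DrugEventProfile:
    drug: str
    n_drug_sentences: int
    events: Dict[str, Tuple[int, ProportionEstimate]]


def proportion_ci(
    count: int, n: int, method: str = "wald", level: float = 0.95
) -> ProportionEstimate:
    """Binomial point estimate and CI for count successes in n trials."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= count <= n):
        raise ValueError("count must lie in [0, n]")
    if method not in ("wald", "wilson"):
        raise ValueError(f"unknown CI method: {method!r}")
    alpha = 1 - level
    sm_method = "normal" if method == "wald" else "wilson"
    low, high = proportion_confint(count, n, alpha=alpha, method=sm_method)
    p_hat = count / n
    # Wald at the boundaries degenerates to a zero-width interval
    return ProportionEstimate(
        p_hat=p_hat,
        ci_low=min(max(float(low), 0.0), p_hat),
        ci_high=max(min(float(high), 1.0), p_hat),
        n=n,
        method=method,
    )


def extract_pairs(
    ade_sentences: Sequence[SentenceRecord], drugs: Lexicon, events: Lexicon
) -> List[DrugEventPair]:
    """Count within-sentence (drug, event) co-mentions across ADE sentences.

    Every (matched drug, matched event) combination in a sentence adds one
    to that pair's count. Output is sorted by (drug, event) for a stable
    order.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for rec in ade_sentences:
        drug_hits = match_terms(rec.tokens, drugs)
        if not drug_hits:
            continue
        event_hits = match_terms(rec.tokens, events)
        for d in drug_hits:
            for e in event_hits:
                counts[(d, e)] = counts.get((d, e), 0) + 1
    return [
        DrugEventPair(drug=d, event=e, count=c)
        for (d, e), c in sorted(counts.items())
    ]


def count_drug_sentences(
    sentences: Sequence[SentenceRecord], drugs: Lexicon
) -> Dict[str, int]:
    """Number of sentences mentioning each drug (once per sentence)."""
    counts: Dict[str, int] = {}
    for rec in sentences:
        for d in match_terms(rec.tokens, drugs):
            counts[d] = counts.get(d, 0) + 1
    return counts


def drug_profile(
    pairs: Sequence[DrugEventPair],
    drugs_sentence_counts: Mapping[str, int],
    drug: str,
    ci_method: str = "wald",
    level: float = 0.95,
) -> DrugEventProfile:
    """Per-drug event counts with Pr(event | drug) estimates and CIs.

    ``n_drug_sentences`` is the denominator: sentences mentioning the drug.
    A sentence can mention several events, so event counts may sum past n,
    but each individual count is capped by it.
    """
    if drug not in drugs_sentence_counts:
        raise ValueError(f"drug {drug!r} absent from sentence counts")
    n = drugs_sentence_counts[drug]
    if n == 0:
        raise ValueError(f"drug {drug!r} has zero observed sentences")
    events: Dict[str, Tuple[int, ProportionEstimate]] = {}
    for pair in pairs:
        if pair.drug != drug:
            continue
        events[pair.event] = (
            pair.count,
            proportion_ci(pair.count, n, method=ci_method, level=level),
        )
    return DrugEventProfile(drug=drug, n_drug_sentences=n, events=events)


def cooccurrence_table(pairs: Sequence[DrugEventPair]) -> pd.DataFrame:
    """Dense drugs x events count matrix (zero cells included)."""
    if not pairs:
        return pd.DataFrame()
    drugs = sorted({p.drug for p in pairs})
    events = sorted({p.event for p in pairs})
    table = pd.DataFrame(0, index=drugs, columns=events, dtype=int)
    for p in pairs:
        table.loc[p.drug, p.event] += p.count
    table.index.name = "drug"
    table.columns.name = "event"
    return table


def wordcloud_frequencies(
    pairs: Sequence[DrugEventPair], drug: str
) -> List[Tuple[str, int]]:
    """Event frequencies for one drug, count descending then lexicographic.

    The list feeds word-cloud style rendering (word size proportional to
    count); an unknown drug yields an empty list rather than an error.
    """
    rows = [(p.event, p.count) for p in pairs if p.drug == drug]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows
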