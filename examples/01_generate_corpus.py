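"""Generate a labeled synthetic ADE corpus and look at what's inside.

The generator plants a known class signal (cue words that co-occur with the
ADE / non-ADE labels), embeds real drug and event lexicon terms, and records
the resulting gold drug-event pairs — so every downstream claim the pipeline
makes can be checked against a known ground truth.
"""

from collections import Counter

from ademiner import synthetic_data as sd
from ademiner.records import Label

corpus = sd.generate_corpus(
    sd.GeneratorConfig(n_sentences=2000, ade_fraction=0.48, label_noise=0.02, seed=0)
)

labels = Counter(r.label for r in corpus.sentences)
print(f"sentences: {len(corpus.sentences)}")
print(f"class balance: {labels[Label.ADE]} ADE / {labels[Label.NO_ADE]} NO_ADE")
print(f"gold drug-event pairs: {len(corpus.gold_pairs)}")

print("\nfirst three sentences:")
for rec in corpus.sentences[:3]:
    print(f"  [{rec.label.value:6s}] {' '.join(rec.tokens)}")

print("\nfive most frequent gold pairs:")
for pair in sorted(corpus.gold_pairs, key=lambda p: -p.count)[:5]:
    print(f"  {pair.drug} -> {pair.event}: {pair.count} sentences")
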