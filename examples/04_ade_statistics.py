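"""Extract drug-event pairs and estimate Pr(event | drug) with intervals.

From ADE-labeled sentences, count in how many sentences each (drug, event)
pair co-occurs, then estimate the conditional probability of each event given
the drug with a binomial confidence interval. The same counts feed a dense
co-occurrence table and word-cloud-style frequency lists.
"""

from ademiner import ade_stats, synthetic_data as sd
from ademiner.corpus_io import default_drug_lexicon, default_event_lexicon
from ademiner.records import Label

corpus = sd.generate_corpus(sd.GeneratorConfig(n_sentences=4000, seed=3))
ade = [r for r in corpus.sentences if r.label is Label.ADE]

drugs, events = default_drug_lexicon(), default_event_lexicon()
pairs = ade_stats.extract_pairs(ade, drugs, events)
counts = ade_stats.count_drug_sentences(ade, drugs)
print(f"{len(ade)} ADE sentences -> {len(pairs)} distinct drug-event pairs")

drug = max(counts, key=counts.get)
profile = ade_stats.drug_profile(pairs, counts, drug, ci_method="wilson")
print(f"\nprofile for {drug} ({profile.n_drug_sentences} sentences):")
for event, (count, est) in sorted(profile.events.items(),
                                  key=lambda kv: -kv[1][0])[:5]:
    print(f"  {event:20s} {count:4d}  Pr={est.p_hat:.3f} "
          f"95% CI ({est.ci_low:.3f}, {est.ci_high:.3f})")

table = ade_stats.cooccurrence_table(pairs)
print(f"\nco-occurrence table: {table.shape[0]} drugs x {table.shape[1]} events")

freqs = ade_stats.wordcloud_frequencies(pairs, drug)
print(f"word-cloud weights for {drug}: {freqs[:3]} ...")
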