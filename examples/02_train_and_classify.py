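"""Train skip-gram embeddings, fit class prototypes, and classify sentences.

The classifier is deliberately simple: a sentence is the mean of its word
vectors, each class is the mean of its training sentences, and a sentence is
assigned to the class whose prototype it is most cosine-similar to. The
cosine margin between the two class scores doubles as a confidence score,
which the self-training step uses to promote machine labels.
"""

from ademiner import evaluation as ev, nn_classifier, synthetic_data as sd
from ademiner.embedding import Hyperparameters, train_skipgram

corpus = sd.generate_corpus(sd.GeneratorConfig(n_sentences=2000, seed=1))
train, test = ev.stratified_split(corpus.sentences, train_frac=0.75, seed=1)

# Smaller than the defaults (dim=98, epochs=25, iterations=10) to keep this
# example quick; accuracy improves with the full settings.
hyper = Hyperparameters(dim=32, epochs=8, iterations=2, seed=1)
model = train_skipgram([r.tokens for r in train], hyper)
print(f"vocabulary after MWF pruning: {len(model.vocab)} words")

prototypes = nn_classifier.fit_prototypes(model, train)
predictions = nn_classifier.classify_many(model, prototypes, test)
accuracy = sum(p.label is r.label for p, r in zip(predictions, test)) / len(test)
print(f"held-out accuracy: {accuracy:.3f} on {len(test)} sentences")

# Self-training: machine-label the most confident unlabeled sentences.
pool = sd.hide_labels(test)
pseudo = nn_classifier.self_train(model, prototypes, pool, confidence_threshold=0.2)
print(f"self-training promoted {len(pseudo)} of {len(pool)} unlabeled sentences")
print(f"highest-margin pseudo-label: {pseudo[0].label.value} "
      f"({' '.join(pseudo[0].tokens)})")
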