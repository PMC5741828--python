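# ademiner

Sentence-level mining of adverse drug events (ADEs) from biomedical text:
a from-scratch skip-gram word-embedding trainer, a cosine-prototype sentence
classifier with semi-supervised self-training, classical bag-of-words
baselines, a full evaluation harness, and drug-event co-occurrence
statistics — plus a synthetic-corpus generator so every piece can be
exercised and verified against a known ground truth.

## What it does

The pipeline takes sentences mentioning drugs and medical events and decides
whether each sentence describes an adverse drug event:

1. **Corpus I/O & preprocessing** (`corpus_io`, `preprocess`) — read documents
   (JSONL or PMC-style XML), normalize text, split sentences, tokenize,
   POS-tag with a built-in rule-based tagger, and keep only candidate
   sentences that mention both a drug and an event from configurable
   lexicons.
2. **Word embeddings** (`embedding`) — skip-gram with negative sampling,
   implemented from scratch (numba-accelerated, single-threaded,
   bit-reproducible). Defaults: 98 dimensions, window 2, 25 epochs,
   10 gradient iterations per sentence, 5 negative samples, and a minimum
   word frequency threshold of 2% of sentences.
3. **Classification** (`nn_classifier`) — a sentence is the mean of its word
   vectors; each class (ADE / NO_ADE) is the mean of its training sentences;
   classification is argmax cosine similarity. The cosine margin doubles as
   a confidence score that drives **self-training**: confident machine labels
   on unlabeled sentences are added to the training set.
4. **Baselines** (`baselines`) — unigram/bigram/POS count features with a
   natively implemented multinomial naive Bayes plus scikit-learn SVM and
   decision-tree wrappers.
5. **Evaluation** (`evaluation`) — stratified splits, stratified k-fold CV,
   accuracy/precision/recall, rank-statistic (Mann–Whitney) ROC AUC, paired
   t-tests, Fleiss' and Cohen's kappa, and learning curves.
6. **ADE statistics** (`ade_stats`) — drug-event pair extraction from
   ADE-labeled sentences, Pr(event | drug) with Wald/Wilson confidence
   intervals, co-occurrence tables, and word-cloud frequency lists.
7. **Synthetic data** (`synthetic_data`) — a first-class generator producing
   labeled corpora with planted class signal, known gold drug-event pairs,
   planted-topic corpora for embedding checks, and simulated rater matrices
   for agreement statistics.

## Quick start (library)

```python
from ademiner import evaluation as ev, nn_classifier, synthetic_data as sd
from ademiner.embedding import Hyperparameters, train_skipgram

corpus = sd.generate_corpus(sd.GeneratorConfig(n_sentences=2000, seed=1))
train, test = ev.stratified_split(corpus.sentences, train_frac=0.75, seed=1)

model = train_skipgram([r.tokens for r in train],
                       Hyperparameters(dim=32, epochs=8, iterations=2, seed=1))
prototypes = nn_classifier.fit_prototypes(model, train)
preds = nn_classifier.classify_many(model, prototypes, test)
accuracy = sum(p.label is r.label for p, r in zip(preds, test)) / len(test)
```

Running `python examples/02_train_and_classify.py` (which is exactly this)
prints, deterministically:

```
vocabulary after MWF pruning: 104 words
held-out accuracy: 0.968 on 500 sentences
self-training promoted 485 of 500 unlabeled sentences
```

and `python examples/03_baselines_and_evaluation.py` cross-validates the
baselines on a 2,000-sentence synthetic corpus:

```
nb            accuracy=0.976 precision=0.978 recall=0.971 auc=0.982
svm           accuracy=0.976 precision=0.977 recall=0.973 auc=0.981
decision_tree accuracy=0.963 precision=0.960 recall=0.964 auc=0.963
```

See `examples/` for four short narrative scripts covering corpus generation,
training/classification, baseline evaluation, and drug-event statistics.

## Quick start (CLI)

```bash
ademiner simulate --n 2000 --seed 0 --out runs/sim
ademiner train    --sentences runs/sim/sentences.jsonl --out runs/model
ademiner classify --model runs/model --sentences runs/sim/sentences.jsonl \
                  --out runs/predictions.jsonl
ademiner evaluate --sentences runs/sim/sentences.jsonl --method proto \
                  --out runs/eval
ademiner extract  --sentences runs/sim/sentences.jsonl --out runs/stats
```

Each subcommand writes its resolved configuration (`resolved_config.yaml`)
next to its outputs; the same config and seed always produce byte-identical
artifacts. `ademiner prepare` converts raw documents into candidate
sentences, and `ademiner baselines` cross-validates all three bag-of-words
models.

## Tests

```bash
python -m pytest -q tests/
```

The suite contains unit tests with closed-form and brute-force oracles plus
`tests/test_acceptance.py`, one test per release criterion (oracle
equivalence of AUC/featurizer/pair extraction, closed-form statistics,
embedding signal recovery against an independent PPMI-SVD factorization,
cross-validated classifier accuracy across seeds, learning-size trend,
self-training sanity, baseline parity, and byte-level determinism of every
pipeline stage). The acceptance tests train full-size embeddings and take
several minutes.

## Documentation

`docs/methods.md` describes the model, the hyperparameters and their
defaults, the synthetic-corpus design, and the numerical/design decisions in
detail.
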