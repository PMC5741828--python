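# Methods

This note documents the models, hyperparameters, synthetic-data design, and
numerical decisions behind `ademiner`.

## Problem setting

Given sentences that mention at least one drug and one medical event (per
configurable lexicons), decide whether each sentence asserts an adverse drug
event (label `ADE`) or not (`NO_ADE`), then aggregate the positive sentences
into drug-event statistics such as Pr(event | drug) with confidence
intervals.

## Preprocessing

- **Normalization** lowercases, strips diacritics (NFKD, dropping combining
  marks), deletes a configurable set of punctuation patterns (brackets,
  quotes, `?`, `!`), and collapses whitespace. Normalization is idempotent.
- **Sentence splitting** is rule-based on `.`/`!`/`?` boundaries with guards
  for decimal numbers, a small abbreviation list (`e.g.`, `i.e.`, `et al.`,
  `vs.`, `fig.`, …), and single-letter initials.
- **Tokenization** keeps maximal alphanumeric runs (`[A-Za-z0-9]+`).
- **POS tagging** uses a deterministic rule-based tagger over a coarse
  11-tag set (NOUN, VERB, ADJ, ADV, PRON, DET, ADP, CONJ, NUM, PART, X): a
  closed-class lexicon first, then suffix rules (`-ing`/`-ed` → VERB, `-ly`
  → ADV, `-ous`/`-ful`/`-ive` → ADJ, digits → NUM, …), defaulting to NOUN.
  It is intentionally coarse — POS features are one of three bag-of-words
  feature families, and only their counts matter.
- **Candidate filtering** keeps sentences that token-boundary-match at least
  one drug and one event term. Multi-word lexicon terms match greedily
  (longest match first) at token granularity.

## Skip-gram embeddings (from scratch)

The embedding trainer implements skip-gram with negative sampling (SGNS):
for a center word c and observed context word o, maximize
`log σ(u_o·v_c) + Σ_{k=1..K} log σ(−u_k·v_c)` with K noise words drawn from
the unigram distribution raised to the 0.75 power.

Implementation choices (all deliberate, standard SGNS conventions):

- Input vectors initialized uniformly in `[−0.5/dim, 0.5/dim]`; output
  (context) vectors initialized to zero.
- Sigmoid evaluated through a 1,000-entry lookup table over `[−6, 6]`.
- Learning rate decays linearly from 0.025 to 0.025/100 over the total
  number of center-context pair updates.
- Negative-sampling table of 10⁶ entries built from unigram^0.75.
- The training loop is a numba-compiled, single-threaded kernel with an
  inline xorshift64 RNG, making training bit-reproducible for a given seed
  across runs and machines (float32 arithmetic, fixed operation order).

### Hyperparameters

| name | default | meaning |
|---|---|---|
| `dim` | 98 | embedding dimensionality |
| `window` (WS) | 2 | symmetric context window in tokens |
| `epochs` (EP) | 25 | full passes over the corpus |
| `iterations` (ITR) | 10 | gradient passes per sentence before moving on |
| `negative_samples` | 5 | noise words per positive pair |
| `learning_rate` | 0.025 | initial learning rate (linear decay) |
| `mwf_percent` (MWF) | 2.0 | minimum word frequency, as % of sentences |
| `seed` | 0 | RNG seed for init and sampling |

`iterations` repeats the gradient updates for each sentence's pairs ITR
times within an epoch — a mini-batch-style intensification that speeds
convergence on small corpora. Effective passes = EP × ITR.

The MWF threshold is interpreted against the sentence count: a token must
appear at least `max(1, ceil(mwf_percent/100 × n_sentences))` times to stay
in the vocabulary (an absolute count `mwf_absolute` can be given instead).
With 2% and a few thousand sentences this is an aggressive filter; it is the
default because the classifier works best when rare noise words are pruned
and every surviving word is trained on many contexts.

## Cosine-prototype classifier and self-training

- Sentence vector = unweighted mean of in-vocabulary word vectors (sentences
  whose words are all out-of-vocabulary get no vector and default to
  `NO_ADE` with margin 0).
- Class prototype = mean of the class's training-sentence vectors.
- Prediction = argmax cosine similarity to the prototypes; the absolute
  difference of the two cosines is the **margin** (confidence).
- Self-training: classify an unlabeled pool, keep predictions with margin ≥
  a threshold (default 0.2, a meaningful bar — on the default synthetic
  corpus trained margins have median ≈ 0.5), order by margin descending
  (ties by sentence id), optionally cap, and add as `machine`-source labels.

## Bag-of-words baselines

Features are counts over three namespaced families — unigrams (`uni:`),
bigrams (`bi:`), POS tags (`pos:`) — with document-frequency pruning
(`min_df`) and a deterministic sorted feature index. Multinomial naive
Bayes is implemented natively (closed-form fit, Laplace smoothing `alpha`,
joint log-likelihood scoring); SVM (RBF) and decision tree wrap
scikit-learn. All models expose `decision_scores` oriented so that higher
means more ADE-like. A constant estimator handles degenerate single-class
training sets.

## Evaluation harness

- Stratified train/test splits and stratified k-fold CV (default k = 4,
  shuffled, seeded).
- Metrics: accuracy, precision, recall from the confusion matrix (precision
  defined as 0 when nothing is predicted positive).
- ROC AUC via the tie-corrected rank (Mann–Whitney) statistic — exactly the
  probability that a random positive outscores a random negative, with ties
  counted half. The ROC curve itself comes from scikit-learn.
- Paired t-test on per-fold metrics (scipy), with explicit handling of the
  degenerate cases: identical inputs → (t=0, p=1); constant nonzero
  difference → (±inf, 0).
- Fleiss' kappa via statsmodels (validated in-tests against the published
  formula), Cohen's kappa via scikit-learn.
- Learning curves: stratified subsample at each requested size, then k-fold
  CV; deterministic per seed.

## ADE statistics

Within ADE-labeled sentences, a (drug, event) pair is counted once per
sentence in which both terms match (presence, not frequency). For a drug
mentioned in n ADE sentences and an event co-mentioned in k of them,
Pr(event | drug) is estimated as k/n with a Wald or Wilson 95% interval
(statsmodels `proportion_confint`, clamped to `[0, 1]` and to contain the
point estimate). Wald is the default for continuity with common practice;
Wilson is recommended for small n or extreme proportions and is available
everywhere (`ci_method="wilson"`). The same pair counts feed a dense
drugs × events co-occurrence table and sorted word-cloud frequency lists.

## Synthetic corpus design

The generator is a first-class module because the pipeline's verification
strategy depends on corpora with known ground truth. Default study
conditions: 8,000 sentences, ADE fraction 0.48, 2% label noise, sentence
length 5–9 tokens. Each sentence is assembled from:

- one drug term (always for ADE; with probability 0.8 for NO_ADE) and one
  event term (always for ADE; with probability 0.8 for NO_ADE) from the
  bundled lexicons (28 drugs, 30 events) — so class membership is **not**
  decidable from lexicon mentions alone;
- class-signal cue words (15 per class), each free slot drawing a cue with
  probability 0.7, otherwise a Zipf-distributed background word (150 types);
- token-level shuffling of the assembled units, then label flips with the
  noise probability.

Class counts are exact quotas; all randomness flows from one
`numpy.random.default_rng` seed; `gold_pairs` are recomputed from the final
(post-noise) ADE labels so they are self-consistent with what a perfect
classifier could recover. The signal strength and vocabulary sizes were
fixed a priori so that content words survive the 2% MWF filter at the
default corpus size; label noise of 2% puts a ceiling of roughly 0.96–0.98
on achievable CV accuracy.

Two auxiliary generators support verification: a **planted-topic corpus**
(disjoint per-topic vocabularies — within-topic words co-occur, cross-topic
words never do) for embedding checks, and a **simulated rater matrix** (with
probability `agreement` all raters copy a latent label, else uniform votes)
for agreement statistics.

## Verification strategy

- Brute-force oracles: AUC against the all-pairs comparison (tolerance
  1e−12), featurizer against direct n-gram counting, pair extraction against
  a nested-loop regex matcher.
- Closed forms: metrics, Wald/Wilson intervals, paired t, Fleiss' kappa
  against hand-computed values; kappa = 1 under perfect agreement and ≈ 0
  under a 10,000-item null simulation.
- Embedding signal: on the planted-topic corpus the trained embeddings must
  separate topics by mean cosine ≥ 0.2 and agree (Spearman ρ ≥ 0.7) with an
  independent count-based PPMI + truncated-SVD factorization — the matrix
  SGNS implicitly factorizes (Levy & Goldberg, 2014).
- End-to-end: stratified 4-fold CV accuracy of the prototype classifier on
  default synthetic corpora across five seeds; learning-size trend at
  reduced epochs (EP=3, ITR=1, chosen a priori — the trend, not the absolute
  level, is under test); self-training never degrading held-out accuracy by
  more than 2 points; byte-identical artifacts for every pipeline stage
  under a fixed seed.

## Scope and limits

- The synthetic corpus emulates the *statistical shape* of an annotated
  pharmacovigilance corpus (class balance, lexicon mentions, noisy labels),
  not its language. Absolute metric values on it do not transfer to real
  biomedical text.
- The rule-based POS tagger and sentence splitter are deliberately simple;
  they are adequate for count features and candidate filtering, not for
  syntax-sensitive downstream use.
- The PMC XML reader handles the common title + paragraph structure only.
- The pipeline is single-threaded by design (determinism over throughput).
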