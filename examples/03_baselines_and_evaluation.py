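"""Cross-validate the bag-of-words baselines and compare them statistically.

Runs stratified 4-fold cross-validation for multinomial naive Bayes, an SVM,
and a decision tree over unigram + bigram + POS count features, then compares
two models' per-fold AUCs with a paired t-test.
"""

from ademiner import evaluation as ev, preprocess, synthetic_data as sd
from ademiner.pipelines import BowPipeline

corpus = sd.generate_corpus(sd.GeneratorConfig(n_sentences=2000, seed=2))
records = corpus.sentences
for rec in records:  # POS features need tags
    rec.pos_tags = preprocess.pos_tag(rec.tokens)

results = {}
for method in ("nb", "svm", "decision_tree"):
    cv = ev.kfold_cv(records, lambda m=method: BowPipeline(classifier=m), k=4, seed=2)
    results[method] = cv
    print(f"{method:13s} accuracy={cv.mean_accuracy:.3f} "
          f"precision={cv.mean_precision:.3f} recall={cv.mean_recall:.3f} "
          f"auc={cv.mean_auc:.3f}")

t, p = ev.paired_t_test(results["nb"].fold_aucs, results["decision_tree"].fold_aucs)
print(f"\nNB vs decision tree, paired t on per-fold AUCs: t={t:.3f} p={p:.4f}")

sizes = [500, 1000, 2000]
curve = ev.learning_curve(sizes, lambda: BowPipeline(classifier="nb"), records, seed=2)
print("\nNB learning curve:")
for n, acc in curve:
    print(f"  n={n:5d}: accuracy={acc:.3f}")
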