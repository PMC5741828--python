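import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ademiner import baselines as bl
from ademiner.preprocess import pos_tag
from ademiner.records import Label

from conftest import make_sentence


def featdict(features: bl.SparseFeatures, row: int) -> dict:
    names = features.feature_names()
    m = features.matrix.tocsr()
    lo, hi = m.indptr[row], m.indptr[row + 1]
    return {names[j]: int(v) for j, v in zip(m.indices[lo:hi], m.data[lo:hi])}


class TestFeaturize:
    def test_unigram_counts(self):
        rec = make_sentence("s", ["a", "b", "a"])
        feats = bl.featurize([rec], bl.FeatureSpec(use_unigrams=True, use_bigrams=False, use_pos=False))
        assert featdict(feats, 0) == {"uni:a": 2, "uni:b": 1}

    def test_bigram_counts(self):
        rec = make_sentence("s", ["a", "b", "a"])
        feats = bl.featurize([rec], bl.FeatureSpec(use_unigrams=False, use_bigrams=True, use_pos=False))
        assert featdict(feats, 0) == {"bi:a_b": 1, "bi:b_a": 1}

    def test_pos_requires_tags(self):
        rec = make_sentence("s", ["a", "b"])
        with pytest.raises(ValueError, match="pos_tags"):
            bl.featurize([rec], bl.FeatureSpec(use_unigrams=False, use_bigrams=False, use_pos=True))

    def test_pos_tag_counts(self):
        tokens = ["aspirin", "causes", "bleeding"]
        rec = make_sentence("s", tokens, pos_tags=pos_tag(tokens))
        feats = bl.featurize([rec], bl.FeatureSpec(use_unigrams=False, use_bigrams=False, use_pos=True))
        # "causes" (closed class) and "bleeding" (-ing suffix) both tag VERB
        assert featdict(feats, 0) == {"pos:NOUN": 1, "pos:VERB": 2}

    def test_min_df_prunes(self):
        recs = [make_sentence("s0", ["a", "b"]), make_sentence("s1", ["a", "c"])]
        feats = bl.featurize(recs, bl.FeatureSpec(use_bigrams=False, use_pos=False, min_df=2))
        assert set(feats.feature_index) == {"uni:a"}

    def test_empty_spec_is_error(self):
        with pytest.raises(ValueError):
            bl.FeatureSpec(use_unigrams=False, use_bigrams=False, use_pos=False)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(st.sampled_from("abcd"), min_size=1, max_size=6),
            min_size=1, max_size=10,
        )
    )
    def test_matches_ngram_counting_oracle(self, sentences):
        recs = [make_sentence(f"s{i}", toks) for i, toks in enumerate(sentences)]
        feats = bl.featurize(recs, bl.FeatureSpec(use_pos=False))
        for i, toks in enumerate(sentences):
            expected = {}
            for t in toks:
                expected[f"uni:{t}"] = expected.get(f"uni:{t}", 0) + 1
            for a, b in zip(toks, toks[1:]):
                expected[f"bi:{a}_{b}"] = expected.get(f"bi:{a}_{b}", 0) + 1
            assert featdict(feats, i) == expected

    def test_order_stability_under_permutation(self):
        recs = [make_sentence(f"s{i}", list(t)) for i, t in
                enumerate(["abc", "bcd", "aa", "dd"])]
        feats = bl.featurize(recs, bl.FeatureSpec(use_pos=False))
        perm = [2, 0, 3, 1]
        feats_p = bl.featurize([recs[i] for i in perm], bl.FeatureSpec(use_pos=False))
        assert feats.feature_index == feats_p.feature_index
        for new_row, old_row in enumerate(perm):
            assert featdict(feats_p, new_row) == featdict(feats, old_row)


def _nb_fixture():
    spec = bl.FeatureSpec(use_bigrams=False, use_pos=False)
    recs = [
        make_sentence("d1", ["f1", "f1"], Label.ADE),
        make_sentence("d2", ["f1", "f2"], Label.ADE),
        make_sentence("d3", ["f2", "f2"], Label.NO_ADE),
    ]
    return bl.featurize(recs, spec), [r.label.value for r in recs], spec


class TestMultinomialNB:
    def test_separable_training_accuracy(self):
        recs = [make_sentence(f"a{i}", ["x", "x"], Label.ADE) for i in range(5)] + [
            make_sentence(f"b{i}", ["y", "y"], Label.NO_ADE) for i in range(5)
        ]
        feats = bl.featurize(recs, bl.FeatureSpec(use_pos=False))
        model = bl.train_multinomial_nb(feats, [r.label.value for r in recs])
        assert (model.predict(feats.matrix) == [r.label.value for r in recs]).all()

    def test_single_example_per_class(self):
        recs = [make_sentence("a", ["x"], Label.ADE), make_sentence("b", ["y"], Label.NO_ADE)]
        feats = bl.featurize(recs, bl.FeatureSpec(use_pos=False))
        model = bl.train_multinomial_nb(feats, [r.label.value for r in recs])
        assert list(model.predict(feats.matrix)) == ["ADE", "NO_ADE"]

    def test_hand_computed_log_odds(self):
        # Class A = {f1 f1}, {f1 f2}; class B = {f2 f2}; alpha = 1; query {f1 f2}.
        # log-odds(A vs B) = log(2/1) + log((3+1)/(4+2) / (0+1)/(2+2))
        #                    + log((1+1)/(4+2) / (2+1)/(2+2)) = log(64/27)
        feats, labels, spec = _nb_fixture()
        model = bl.train_multinomial_nb(feats, labels, alpha=1.0)
        query = bl.featurize(
            [make_sentence("q", ["f1", "f2"])], spec, feature_index=feats.feature_index
        )
        jll = model.joint_log_likelihood(query.matrix)[0]
        log_odds_ade = jll[0] - jll[1]  # classes sorted: ADE, NO_ADE
        assert log_odds_ade == pytest.approx(math.log(64 / 27), abs=1e-12)

    def test_alpha_to_zero_approaches_mle_decision(self):
        # With f1 only ever in class A and f2 only in B, the alpha->0 NB
        # decision matches the empirical class-conditional MLE: each word
        # deterministically indicates its class.
        recs = [
            make_sentence("a1", ["f1"], Label.ADE),
            make_sentence("a2", ["f1"], Label.ADE),
            make_sentence("b1", ["f2"], Label.NO_ADE),
        ]
        spec = bl.FeatureSpec(use_bigrams=False, use_pos=False)
        feats = bl.featurize(recs, spec)
        model = bl.train_multinomial_nb(feats, [r.label.value for r in recs], alpha=1e-10)
        q = bl.featurize(
            [make_sentence("q1", ["f1"]), make_sentence("q2", ["f2"])],
            spec, feature_index=feats.feature_index,
        )
        assert list(model.predict(q.matrix)) == ["ADE", "NO_ADE"]
        # log-odds magnitude explodes as alpha -> 0 (MLE puts zero mass cross-class)
        assert abs(model.decision_scores(q.matrix)[0]) > 10

    def test_unseen_feature_never_errors(self):
        feats, labels, spec = _nb_fixture()
        model = bl.train_multinomial_nb(feats, labels)
        q = bl.featurize([make_sentence("q", ["novel"])], spec,
                         feature_index=feats.feature_index)
        assert model.predict(q.matrix).shape == (1,)


class TestTrainExternal:
    def test_svm_separates_toy_features(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(20):
            recs.append(make_sentence(f"a{i}", ["left"] * int(rng.integers(2, 5)), Label.ADE))
            recs.append(make_sentence(f"b{i}", ["right"] * int(rng.integers(2, 5)), Label.NO_ADE))
        feats = bl.featurize(recs, bl.FeatureSpec(use_pos=False))
        labels = [r.label.value for r in recs]
        model = bl.train_external("svm", feats, labels)
        assert (model.predict(feats.matrix) == labels).all()

    def test_constant_labels_predict_constant(self):
        recs = [make_sentence(f"s{i}", ["w"], Label.ADE) for i in range(4)]
        feats = bl.featurize(recs, bl.FeatureSpec(use_pos=False))
        model = bl.train_external("decision_tree", feats, ["ADE"] * 4)
        assert (model.predict(feats.matrix) == "ADE").all()

    def test_unknown_kind_is_error(self):
        feats, labels, _ = _nb_fixture()
        with pytest.raises(ValueError, match="unknown"):
            bl.train_external("mystery", feats, labels)

    def test_smoke_on_synthetic_corpus(self, small_corpus):
        recs = small_corpus.sentences[:200]
        for r in recs:
            if not r.pos_tags:
                r.pos_tags = pos_tag(r.tokens)
        feats = bl.featurize(recs)
        labels = [r.label.value for r in recs]
        for kind in ("svm", "decision_tree"):
            model = bl.train_external(kind, feats, labels)
            acc = (model.predict(feats.matrix) == labels).mean()
            assert 0.0 <= acc <= 1.0
            assert model.decision_scores(feats.matrix).shape == (len(recs),)
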