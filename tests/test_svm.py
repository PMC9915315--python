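"""TF-IDF fidelity, vocabulary building, training, cross-validation hygiene."""

import math

import numpy as np
import pytest

from mrim.pipeline import tokenize_corpus
from mrim.svm import (
    build_vocabulary,
    classify,
    classify_many,
    cross_validate,
    load_model,
    save_model,
    tfidf_weight,
    train,
    transform,
    vectorize,
)
from mrim.synth import GeneratorSpec, generate_corpus


class TestBuildVocabulary:
    def test_total_frequency_threshold(self):
        model = build_vocabulary([["a", "a", "a"], ["b"]], min_term_freq=3)
        assert set(model.vocabulary) == {"a"}
        assert model.doc_freq[model.vocabulary["a"]] == 1
        assert model.corpus_size == 2

    def test_threshold_one_keeps_everything(self):
        model = build_vocabulary([["a", "a", "a"], ["b"]], min_term_freq=1)
        assert set(model.vocabulary) == {"a", "b"}

    def test_ubiquitous_term_doc_freq_equals_corpus_size(self):
        docs = [["flood", f"w{i}"] for i in range(10)]
        model = build_vocabulary(docs, min_term_freq=3)
        assert model.doc_freq[model.vocabulary["flood"]] == 10 == model.corpus_size

    def test_empty_corpus_and_empty_vocabulary_errors(self):
        with pytest.raises(ValueError):
            build_vocabulary([], min_term_freq=3)
        with pytest.raises(ValueError, match="min_term_freq"):
            build_vocabulary([["a"], ["b"]], min_term_freq=3)


class TestTfidfWeight:
    @pytest.fixture()
    def model(self):
        # |D| = 10; "flood" in 4 docs; "water" in all 10; unseen df = 0
        docs = [["flood", "water"] + ["x"] * 3] * 4 + [["water", "y", "y", "y"]] * 6
        return build_vocabulary(docs, min_term_freq=1)

    def test_hand_evaluated_weight(self, model):
        doc = ["flood", "flood"] + ["pad"] * 6  # n=2 of 8 tokens
        tf = 2 / 8
        idf = math.log10(10 / (1 + 4))
        assert tfidf_weight("flood", doc, model) == pytest.approx(tf * idf, abs=1e-12)
        assert idf == pytest.approx(0.301030, abs=1e-6)

    def test_ubiquitous_term_gets_negative_idf(self, model):
        assert model.idf_of("water") == pytest.approx(math.log10(10 / 11), abs=1e-12)
        assert model.idf_of("water") < 0

    def test_unseen_term_idf_is_one(self, model):
        assert model.idf_of("unseen") == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative_switch_clamps(self, model):
        model.nonnegative_idf = True
        assert model.idf_of("water") == 0.0

    def test_empty_document_is_zero_vector(self, model):
        assert tfidf_weight("flood", [], model) == 0.0
        assert vectorize([], model) == {}

    def test_matches_naive_two_pass_recount_oracle(self, lexicons):
        corpus, _ = generate_corpus(GeneratorSpec(n=60, seed=9), lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        model = build_vocabulary(docs, min_term_freq=3)
        # naive recount: two explicit passes over raw token lists
        D = len(docs)
        for j in (0, 7, 31, 59):
            doc = docs[j]
            for term in set(doc) & set(model.vocabulary):
                tf = doc.count(term) / len(doc)
                df = sum(1 for d in docs if term in d)
                expected = tf * math.log10(D / (1 + df))
                assert tfidf_weight(term, doc, model) == pytest.approx(expected, abs=1e-12)


class TestVectorize:
    def test_oov_only_doc_is_empty_but_counts_in_denominator(self):
        model = build_vocabulary([["a"], ["a"], ["a"]], min_term_freq=3)
        assert vectorize(["zz", "qq"], model) == {}
        vec = vectorize(["a", "zz"], model)  # OOV inflates the tf denominator
        assert vec[model.vocabulary["a"]] == pytest.approx(0.5 * model.idf_of("a"))

    def test_single_term_doc(self):
        model = build_vocabulary([["a"], ["a"], ["a"], ["b"]], min_term_freq=3)
        vec = vectorize(["a"], model)
        assert vec == {model.vocabulary["a"]: pytest.approx(1.0 * model.idf_of("a"))}

    def test_consistent_with_elementwise_tfidf_weight(self, lexicons):
        corpus, _ = generate_corpus(GeneratorSpec(n=40, seed=2), lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        model = build_vocabulary(docs, min_term_freq=2)
        X = transform(docs, model)
        for j, doc in enumerate(docs):
            for term, col in model.vocabulary.items():
                assert X[j, col] == pytest.approx(tfidf_weight(term, doc, model), abs=1e-12)


def _toy_separable(n=60):
    rng = np.random.default_rng(0)
    docs, labels = [], []
    for i in range(n):
        y = i % 2
        tok = "rescue" if y else "chatter"
        docs.append([tok] * 3 + [f"noise{rng.integers(5)}"])
        labels.append(y)
    return docs, labels


class TestTrainClassify:
    def test_separable_corpus_fits_perfectly(self):
        docs, labels = _toy_separable()
        clf = train(docs, labels, min_term_freq=1)
        pred, scores = classify_many(clf, docs)
        assert (pred == labels).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train([["a"], ["a"]], [1, 1], min_term_freq=1)

    def test_score_is_hundred_times_label(self):
        docs, labels = _toy_separable()
        clf = train(docs, labels, min_term_freq=1)
        for doc in (["rescue"], ["chatter"], ["nothing"]):
            label, score = classify(clf, doc)
            assert score == 100 * label

    def test_classify_idempotent_and_deterministic(self, lexicons):
        corpus, _ = generate_corpus(GeneratorSpec(n=300, seed=4), lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        y = [p.label for p in corpus]
        a = train(docs, y, seed=3)
        b = train(docs, y, seed=3)
        pa, _ = classify_many(a, docs)
        pb, _ = classify_many(b, docs)
        assert (pa == pb).all()

    def test_model_round_trips_through_persistence(self, tmp_path):
        docs, labels = _toy_separable()
        clf = train(docs, labels, min_term_freq=1)
        path = tmp_path / "model.json"
        save_model(clf, path)
        back = load_model(path)
        pa, sa = classify_many(clf, docs)
        pb, sb = classify_many(back, docs)
        assert (pa == pb).all() and (sa == sb).all()


class TestCrossValidate:
    def test_fold_sizes_at_7979(self):
        """10 folds of a 7979-record corpus are sized 797 or 798."""
        y = np.zeros(7979, dtype=int)
        y[:1936] = 1
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        sizes = sorted(len(test) for _, test in skf.split(np.zeros(7979), y))
        assert set(sizes) == {797, 798} and sum(sizes) == 7979

    def test_partition_property_and_pooled_metrics(self, lexicons):
        corpus, _ = generate_corpus(GeneratorSpec(n=300, seed=4), lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        y = np.array([p.label for p in corpus])
        cv = cross_validate(docs, y, k=5, seed=0)
        all_test = np.concatenate(cv.fold_test_indices)
        assert sorted(all_test.tolist()) == list(range(len(y)))  # disjoint, exhaustive
        assert (cv.oof_labels >= 0).all()
        total = sum(c.n for c in cv.fold_confusions)
        assert total == len(y)

    def test_perfectly_separable_corpus_pools_to_f_one(self):
        docs, labels = _toy_separable(80)
        cv = cross_validate(docs, np.asarray(labels), k=4, seed=0, min_term_freq=1)
        assert cv.f_measure == pytest.approx(1.0)

    def test_perfect_classifier_stub_scores_one(self):
        class GoldStub:
            """Plug-in classifier that memorizes gold labels by vector identity."""

            def fit(self, X, y):
                self._seen = {X[i].toarray().tobytes(): y[i] for i in range(X.shape[0])}
                self._default = int(np.bincount(y).argmax())
                return self

            def predict(self, X):
                return np.array(
                    [
                        self._seen.get(X[i].toarray().tobytes(), self._default)
                        for i in range(X.shape[0])
                    ]
                )

        docs, labels = _toy_separable(80)
        cv = cross_validate(
            docs,
            np.asarray(labels),
            k=4,
            seed=0,
            min_term_freq=1,
            classifier_factory=lambda C, seed: GoldStub(),
        )
        # held-out vectors of this toy construction repeat across folds
        assert cv.f_measure == pytest.approx(1.0)

    def test_no_leakage_corrupting_heldout_labels_changes_nothing(self, lexicons):
        corpus, _ = generate_corpus(GeneratorSpec(n=240, seed=6), lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        y = np.array([p.label for p in corpus])
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        splits = [(idx[60:], idx[:60])]
        cv1 = cross_validate(docs, y, splits=splits)
        y_corrupt = y.copy()
        y_corrupt[idx[:60]] = rng.integers(0, 2, size=60)  # held-out fold only
        cv2 = cross_validate(docs, y_corrupt, splits=splits)
        assert (cv1.oof_labels[idx[:60]] == cv2.oof_labels[idx[:60]]).all()

    def test_permuted_labels_score_near_chance(self, lexicons):
        corpus, _ = generate_corpus(GeneratorSpec(n=400, seed=8), lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        y = np.array([p.label for p in corpus])
        rng = np.random.default_rng(1)
        y_perm = rng.permutation(y)
        cv = cross_validate(docs, y_perm, k=5, seed=0)
        r = y_perm.mean()
        q = cv.oof_labels.mean()
        chance_f = 2 * r * q / (r + q) if r + q > 0 else 0.0
        assert abs(cv.f_measure - chance_f) <= 0.1

    def test_default_synthetic_corpus_learnable(self, lexicons):
        """Planted token signal must be recoverable: CV F above 0.5."""
        corpus, _ = generate_corpus(GeneratorSpec(n=1200, seed=5), lexicons)
        docs = tokenize_corpus(corpus, lexicons.extraction_resources())
        y = [p.label for p in corpus]
        cv = cross_validate(docs, y, k=5, seed=0)
        assert cv.f_measure > 0.5
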