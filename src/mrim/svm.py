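"""TF-IDF + linear maximum-margin text classifier.

The term weighting follows the study's printed formulas exactly:

    tf(i, j)    = n(i, j) / sum_k n(k, j)
    idf(i)      = log10( |D| / (1 + df(i)) )
    tfidf(i, j) = tf(i, j) * idf(i)

where the tf denominator counts *all* tokens of document j (including
out-of-vocabulary ones), |D| is the number of training documents and
df(i) the number of training documents containing term i.  Note the +1 in
the idf denominator: a term present in every document gets a slightly
negative idf and an unseen term gets log10(|D|); both are kept as printed
(``nonnegative_idf=True`` clamps at zero for callers who want the more
common variant).  No length normalization is applied.

The vocabulary is unigram with a minimum total-occurrence count (default
3).  The decision rule is a linear-kernel SVM (scikit-learn's LinearSVC).
Because the printed weighting is NOT length-normalized, short-text vectors
have small norms (tf <= 1/len(doc)); the default regularization C = 10
compensates for that scale -- unit C, which presumes unit-scale features,
collapses the fit toward the majority class.  A prediction of useful maps
to SVM_Score 100, useless to 0.  ``classifier_factory`` makes the learner
pluggable (e.g. naive Bayes or a decision tree) behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .evaluate import ConfusionCounts, confusion, precision_recall_f

__all__ = [
    "CVResult",
    "TextClassifier",
    "TfidfModel",
    "build_vocabulary",
    "classify",
    "classify_many",
    "cross_validate",
    "load_model",
    "save_model",
    "tfidf_weight",
    "train",
    "transform",
    "vectorize",
]

TokenDocs = Sequence[Sequence[str]]


@dataclass
class TfidfModel:
    """Vocabulary, document frequencies and corpus size of a fitted TF-IDF."""

    vocabulary: dict[str, int]
    doc_freq: np.ndarray
    corpus_size: int
    min_term_freq: int = 3
    nonnegative_idf: bool = False

    @property
    def idf(self) -> np.ndarray:
        idf = np.log10(self.corpus_size / (1.0 + self.doc_freq))
        if self.nonnegative_idf:
            idf = np.maximum(idf, 0.0)
        return idf

    def idf_of(self, term: str) -> float:
        """idf of any term, seen or unseen (df = 0 for unseen terms)."""
        col = self.vocabulary.get(term)
        df = float(self.doc_freq[col]) if col is not None else 0.0
        idf = np.log10(self.corpus_size / (1.0 + df))
        return float(max(idf, 0.0)) if self.nonnegative_idf else float(idf)


def build_vocabulary(
    tokenized_docs: TokenDocs,
    min_term_freq: int = 3,
    *,
    freq_mode: str = "total",
    nonnegative_idf: bool = False,
) -> TfidfModel:
    """Fit vocabulary and document frequencies on tokenized training docs.

    ``freq_mode='total'`` (default) reads the minimum-frequency threshold
    as total occurrence count across the corpus; ``'document'`` reads it
    as document frequency.
    """
    if len(tokenized_docs) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if freq_mode not in ("total", "document"):
        raise ValueError("freq_mode must be 'total' or 'document'")
    total: dict[str, int] = {}
    docfreq: dict[str, int] = {}
    for doc in tokenized_docs:
        for tok in doc:
            total[tok] = total.get(tok, 0) + 1
        for tok in set(doc):
            docfreq[tok] = docfreq.get(tok, 0) + 1
    counts = total if freq_mode == "total" else docfreq
    kept = sorted(t for t, c in counts.items() if c >= min_term_freq)
    if not kept:
        raise ValueError(
            "vocabulary is empty after frequency filtering; lower min_term_freq"
        )
    vocabulary = {t: i for i, t in enumerate(kept)}
    df = np.array([docfreq[t] for t in kept], dtype=float)
    return TfidfModel(
        vocabulary=vocabulary,
        doc_freq=df,
        corpus_size=len(tokenized_docs),
        min_term_freq=min_term_freq,
        nonnegative_idf=nonnegative_idf,
    )


def tfidf_weight(term: str, doc_tokens: Sequence[str], model: TfidfModel) -> float:
    """tf * idf of one term in one document (0.0 for an empty document)."""
    n_total = len(doc_tokens)
    if n_total == 0:
        return 0.0
    n_term = sum(1 for t in doc_tokens if t == term)
    tf = n_term / n_total
    return tf * model.idf_of(term)


def vectorize(doc_tokens: Sequence[str], model: TfidfModel) -> dict[int, float]:
    """Sparse map column -> weight for one document.

    Out-of-vocabulary tokens contribute no entry but do count in the tf
    denominator.
    """
    n_total = len(doc_tokens)
    if n_total == 0:
        return {}
    counts: dict[int, int] = {}
    for tok in doc_tokens:
        col = model.vocabulary.get(tok)
        if col is not None:
            counts[col] = counts.get(col, 0) + 1
    idf = model.idf
    return {col: (n / n_total) * idf[col] for col, n in counts.items()}


def transform(tokenized_docs: TokenDocs, model: TfidfModel) -> sp.csr_matrix:
    """TF-IDF matrix (documents x vocabulary) as CSR."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for doc in tokenized_docs:
        vec = vectorize(doc, model)
        indices.extend(vec.keys())
        data.extend(vec.values())
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data, dtype=float), np.asarray(indices, dtype=np.int32), indptr),
        shape=(len(tokenized_docs), len(model.vocabulary)),
    )


def _default_factory(C: float, seed: int) -> LinearSVC:
    return LinearSVC(C=C, random_state=seed)


@dataclass
class TextClassifier:
    """Fitted TF-IDF model plus linear decision rule; useful -> score 100."""

    tfidf: TfidfModel
    estimator: object
    svm_score_map: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 100})


def train(
    tokenized_docs: TokenDocs,
    labels: Sequence[int],
    *,
    min_term_freq: int = 3,
    C: float = 10.0,
    seed: int = 0,
    nonnegative_idf: bool = False,
    classifier_factory: Callable[..., object] | None = None,
) -> TextClassifier:
    """Fit the TF-IDF model and the margin classifier on labeled documents.

    Deterministic given fixed seed and data order.  Raises on a
    single-class training set.
    """
    y = np.asarray(labels, dtype=int)
    if len(tokenized_docs) != len(y):
        raise ValueError("documents and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = build_vocabulary(
        tokenized_docs, min_term_freq=min_term_freq, nonnegative_idf=nonnegative_idf
    )
    X = transform(tokenized_docs, model)
    est = (
        classifier_factory(C=C, seed=seed)
        if classifier_factory is not None
        else _default_factory(C, seed)
    )
    est.fit(X, y)
    return TextClassifier(tfidf=model, estimator=est)


def save_model(clf: TextClassifier, path) -> None:
    """Persist a trained classifier as self-describing JSON.

    Captures the vocabulary, document frequencies, |D| and the linear
    separator's coefficients; only LinearSVC-backed classifiers are
    persistable.
    """
    import json
    from pathlib import Path

    est = clf.estimator
    if not isinstance(est, LinearSVC):
        raise TypeError("only the default linear-SVM estimator can be persisted")
    payload = {
        "format": "mrim-text-classifier-v1",
        "vocabulary": clf.tfidf.vocabulary,
        "doc_freq": clf.tfidf.doc_freq.tolist(),
        "corpus_size": clf.tfidf.corpus_size,
        "min_term_freq": clf.tfidf.min_term_freq,
        "nonnegative_idf": clf.tfidf.nonnegative_idf,
        "coef": est.coef_.ravel().tolist(),
        "intercept": float(est.intercept_[0]),
        "classes": est.classes_.tolist(),
        "svm_score_map": {str(k): v for k, v in clf.svm_score_map.items()},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path) -> TextClassifier:
    """Load a classifier persisted by :func:`save_model`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "mrim-text-classifier-v1":
        raise ValueError("not a persisted mrim text classifier")
    model = TfidfModel(
        vocabulary={k: int(v) for k, v in payload["vocabulary"].items()},
        doc_freq=np.asarray(payload["doc_freq"], dtype=float),
        corpus_size=int(payload["corpus_size"]),
        min_term_freq=int(payload["min_term_freq"]),
        nonnegative_idf=bool(payload["nonnegative_idf"]),
    )
    est = LinearSVC()
    est.coef_ = np.asarray([payload["coef"]], dtype=float)
    est.intercept_ = np.asarray([payload["intercept"]], dtype=float)
    est.classes_ = np.asarray(payload["classes"])
    return TextClassifier(
        tfidf=model,
        estimator=est,
        svm_score_map={int(k): int(v) for k, v in payload["svm_score_map"].items()},
    )


def classify(clf: TextClassifier, doc_tokens: Sequence[str]) -> tuple[int, int]:
    """(label, SVM_Score) for one document; score is exactly 100 * label."""
    labels, scores = classify_many(clf, [doc_tokens])
    return int(labels[0]), int(scores[0])


def classify_many(clf: TextClassifier, tokenized_docs: TokenDocs) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and 0/100 scores for many documents."""
    X = transform(tokenized_docs, clf.tfidf)
    labels = np.asarray(clf.estimator.predict(X), dtype=int)
    scores = np.array([clf.svm_score_map[int(l)] for l in labels], dtype=int)
    return labels, scores


@dataclass
class CVResult:
    """Cross-validation output: per-fold counts, pooled metrics, OOF predictions."""

    fold_confusions: list[ConfusionCounts]
    pooled: ConfusionCounts
    precision: float
    recall: float
    f_measure: float
    oof_labels: np.ndarray
    oof_scores: np.ndarray
    fold_test_indices: list[np.ndarray]


def cross_validate(
    tokenized_docs: TokenDocs,
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
    *,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    min_term_freq: int = 3,
    C: float = 10.0,
    nonnegative_idf: bool = False,
    classifier_factory: Callable[..., object] | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation with no vocabulary leakage.

    The vocabulary, document frequencies and classifier are rebuilt inside
    each training fold; held-out documents never influence the model that
    predicts them.  Returns per-fold confusion counts, pooled
    precision/recall/F over the out-of-fold (OOF) predictions, and the OOF
    label/score vectors aligned with the input order.  ``splits`` may
    supply precomputed (train_idx, test_idx) pairs.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if splits is None:
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise ValueError(
                f"stratified {k}-fold needs >= {k} records of each class, got {counts.tolist()}"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), y))
    oof_labels = np.full(n, -1, dtype=int)
    oof_scores = np.zeros(n, dtype=int)
    fold_confusions: list[ConfusionCounts] = []
    fold_test_indices: list[np.ndarray] = []
    for fold_seed, (train_idx, test_idx) in enumerate(splits):
        clf = train(
            [tokenized_docs[i] for i in train_idx],
            y[train_idx],
            min_term_freq=min_term_freq,
            C=C,
            seed=seed + fold_seed,
            nonnegative_idf=nonnegative_idf,
            classifier_factory=classifier_factory,
        )
        pred, scores = classify_many(clf, [tokenized_docs[i] for i in test_idx])
        oof_labels[test_idx] = pred
        oof_scores[test_idx] = scores
        fold_confusions.append(confusion(y[test_idx], pred))
        fold_test_indices.append(np.asarray(test_idx))
    covered = oof_labels >= 0  # custom splits may cover only part of the data
    pooled = confusion(y[covered], oof_labels[covered])
    p, r, f = precision_recall_f(pooled)
    return CVResult(
        fold_confusions=fold_confusions,
        pooled=pooled,
        precision=p,
        recall=r,
        f_measure=f,
        oof_labels=oof_labels,
        oof_scores=oof_scores,
        fold_test_indices=fold_test_indices,
    )
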