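"""End-to-end experiment: generate/load -> extract -> classify -> integrate -> evaluate.

Reproduces the study protocol on a labeled corpus: the text arm is
evaluated by stratified tenfold cross-validation (each post predicted by a
model that never saw it), the rule arm needs no training, and MRIM is the
union of the two verdicts on the same posts.  The weighted-score
alternative is swept over w in [0, 1].  All randomness flows from one
seed, so a fixed seed yields a byte-identical report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus
from .evaluate import (
    ADDRESS_CONTACT_GROUPS,
    confusion,
    group_by_address_contact,
    group_by_attention_deciles,
    group_by_word_count_deciles,
    grouped_evaluation,
    precision_recall_f,
)
from .features import ExtractionResources, extract_features_frame, strip_markup, tokenize
from .integrate import integrate_union_many, sweep_weight
from .rules import DEFAULT_RULE_CONFIG, RuleConfig, score_corpus
from .svm import cross_validate
from .synth import GeneratorSpec, LexiconSet, generate_corpus, generate_lexicons

__all__ = ["ExperimentReport", "run_experiment", "tokenize_corpus"]


def tokenize_corpus(corpus: Corpus, resources: ExtractionResources) -> list[list[str]]:
    """Stop-word-filtered token lists for the text classifier."""
    stop = resources.tokenizer.stop_words
    return [
        [
            t
            for t in tokenize(strip_markup(p.text, resources.markup_patterns), resources.tokenizer)
            if t not in stop
        ]
        for p in corpus
    ]


@dataclass
class ExperimentReport:
    """Per-method metrics, the w-sweep and the three grouped analyses."""

    methods: pd.DataFrame          # index: method; columns: precision/recall/f_measure + counts
    sweep: pd.DataFrame            # w, precision, recall, f_measure
    best_w: float
    by_word_count: pd.DataFrame    # grouped evaluation tables
    by_address_contact: pd.DataFrame
    by_attention: pd.DataFrame
    word_count_group_means: list[float]
    n: int
    seed: int

    def to_json(self) -> str:
        """Canonical (deterministic, sorted-keys) JSON rendering."""
        payload = {
            "n": self.n,
            "seed": self.seed,
            "best_w": self.best_w,
            "methods": self.methods.round(10).to_dict(orient="index"),
            "sweep": self.sweep.round(10).to_dict(orient="records"),
            "by_word_count": self.by_word_count.round(10).to_dict(orient="records"),
            "by_address_contact": self.by_address_contact.round(10).to_dict(orient="records"),
            "by_attention": self.by_attention.round(10).to_dict(orient="records"),
            "word_count_group_means": [round(x, 10) for x in self.word_count_group_means],
        }
        return json.dumps(payload, sort_keys=True, ensure_ascii=False, indent=1)


def _method_row(gold: np.ndarray, pred: np.ndarray) -> dict:
    counts = confusion(gold, pred)
    p, r, f = precision_recall_f(counts)
    return {
        "precision": p,
        "recall": r,
        "f_measure": f,
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "tn": counts.tn,
    }


def run_experiment(
    spec: GeneratorSpec | None = None,
    corpus: Corpus | None = None,
    lexicons: LexiconSet | None = None,
    *,
    cv_folds: int = 10,
    rule_config: RuleConfig = DEFAULT_RULE_CONFIG,
    sweep_grid=None,
    seed: int | None = None,
) -> ExperimentReport:
    """Run the full comparative experiment on a generated or given corpus.

    Either ``spec`` (a corpus is generated) or a labeled ``corpus`` plus
    ``lexicons`` must be supplied.
    """
    if corpus is None:
        if spec is None:
            spec = GeneratorSpec()
        if lexicons is None:
            lexicons = generate_lexicons(spec.seed, spec.n_vocab, spec.n_signal_tokens)
        corpus, _ = generate_corpus(spec, lexicons)
        seed = spec.seed if seed is None else seed
    else:
        if lexicons is None:
            raise ValueError("a corpus needs accompanying lexicons")
        seed = 0 if seed is None else seed

    gold = np.array([p.label for p in corpus], dtype=object)
    if any(l is None for l in gold):
        raise ValueError("experiment needs a fully labeled corpus")
    gold = gold.astype(int)

    resources = lexicons.extraction_resources()
    features = extract_features_frame(corpus, resources)
    rule_table = score_corpus(corpus, features, rule_config)
    rule_labels = rule_table["rule_label"].to_numpy()
    rule_scores = rule_table["rule_score"].to_numpy()

    docs = tokenize_corpus(corpus, resources)
    cv = cross_validate(docs, gold, k=cv_folds, seed=seed)
    svm_labels, svm_scores = cv.oof_labels, cv.oof_scores

    mrim_labels = integrate_union_many(svm_labels, rule_labels)

    methods = pd.DataFrame(
        {
            "svm": _method_row(gold, svm_labels),
            "rule": _method_row(gold, rule_labels),
            "mrim": _method_row(gold, mrim_labels),
        }
    ).T[["precision", "recall", "f_measure", "tp", "fp", "fn", "tn"]]

    sweep, best_w = sweep_weight(
        gold, svm_scores, rule_scores, grid=sweep_grid, threshold=rule_config.threshold
    )

    predictions = {"svm": svm_labels, "mrim": mrim_labels}
    ids = corpus.ids
    wc_groups, wc_means = group_by_word_count_deciles(
        features["word_count"].to_numpy(), ids
    )
    by_wc = grouped_evaluation(
        wc_groups, [f"decile_{i + 1}" for i in range(10)], gold, predictions
    )
    ac_groups = group_by_address_contact(
        features["has_exact_address"].to_numpy(), features["has_contact"].to_numpy()
    )
    by_ac = grouped_evaluation(ac_groups, list(ADDRESS_CONTACT_GROUPS), gold, predictions)
    att_groups = group_by_attention_deciles(corpus)
    by_att = grouped_evaluation(
        att_groups, [f"decile_{i + 1}" for i in range(10)], gold, predictions
    )

    return ExperimentReport(
        methods=methods,
        sweep=sweep,
        best_w=best_w,
        by_word_count=by_wc,
        by_address_contact=by_ac,
        by_attention=by_att,
        word_count_group_means=wc_means,
        n=len(corpus),
        seed=int(seed),
    )
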