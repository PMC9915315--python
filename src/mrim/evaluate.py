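"""Metrics and grouped analyses.

Precision, recall and F1 with useful = positive, plus the three grouped
views of classifier performance used in the study protocol: ten rank-based
word-count deciles, four address/contact groups (both, contact-only,
address-only, neither), and ten attention deciles (attention = likes +
comments + shares).

Decile boundaries are by rank, not by value quantiles: records are sorted
ascending by the key (ties broken by id for determinism) and split into
ten contiguous groups; when n is not divisible by 10 the smaller groups
come first (7979 records -> one group of 797 then nine of 798).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "decile_groups",
    "group_by_address_contact",
    "group_by_attention_deciles",
    "group_by_word_count_deciles",
    "grouped_evaluation",
    "precision_recall_f",
]

ADDRESS_CONTACT_GROUPS = ("both", "contact_only", "address_only", "neither")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(gold: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Confusion counts over aligned gold/predicted binary vectors."""
    g = np.asarray(gold, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if g.shape != p.shape:
        raise ValueError("gold and predicted labels differ in length")
    if not (np.isin(g, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(np.sum((g == 1) & (p == 1))),
        fp=int(np.sum((g == 0) & (p == 1))),
        fn=int(np.sum((g == 1) & (p == 0))),
        tn=int(np.sum((g == 0) & (p == 0))),
    )


def precision_recall_f(counts: ConfusionCounts) -> tuple[float, float, float]:
    """P = tp/(tp+fp), R = tp/(tp+fn), F = 2PR/(P+R); 0 on empty denominators."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def decile_groups(
    keys: Sequence[float], ids: Sequence[str], n_groups: int = 10
) -> list[np.ndarray]:
    """Rank-based contiguous groups sorted ascending by key (tie-break: id).

    Returns a list of index arrays into the input order; smaller remainder
    groups come first.
    """
    keys = np.asarray(keys)
    n = len(keys)
    if len(ids) != n:
        raise ValueError("keys and ids differ in length")
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} records, got {n}")
    order = sorted(range(n), key=lambda i: (keys[i], str(ids[i])))
    base, rem = divmod(n, n_groups)
    sizes = [base] * (n_groups - rem) + [base + 1] * rem
    groups = []
    start = 0
    for size in sizes:
        groups.append(np.asarray(order[start : start + size], dtype=int))
        start += size
    return groups


def group_by_word_count_deciles(
    word_counts: Sequence[int], ids: Sequence[str]
) -> tuple[list[np.ndarray], list[float]]:
    """Ten word-count deciles; also reports each group's mean word count."""
    groups = decile_groups(word_counts, ids)
    wc = np.asarray(word_counts, dtype=float)
    return groups, [float(wc[g].mean()) for g in groups]


def group_by_attention_deciles(corpus, ids: Sequence[str] | None = None) -> list[np.ndarray]:
    """Ten deciles keyed on attention = likes + comments + shares."""
    attention = [p.likes + p.comments + p.shares for p in corpus]
    if ids is None:
        ids = [p.id for p in corpus]
    return decile_groups(attention, ids)


def group_by_address_contact(
    address_flags: Sequence[int], contact_flags: Sequence[int]
) -> list[np.ndarray]:
    """Four groups in order: both, contact-only, address-only, neither."""
    a = np.asarray(address_flags, dtype=int)
    c = np.asarray(contact_flags, dtype=int)
    if a.shape != c.shape:
        raise ValueError("flag vectors differ in length")
    return [
        np.flatnonzero((a == 1) & (c == 1)),
        np.flatnonzero((a == 0) & (c == 1)),
        np.flatnonzero((a == 1) & (c == 0)),
        np.flatnonzero((a == 0) & (c == 0)),
    ]


def grouped_evaluation(
    groups: Sequence[np.ndarray],
    group_names: Sequence[str],
    gold: Sequence[int],
    predictions: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Per-group, per-method precision/recall/F table.

    Predictions come from globally fitted methods applied per group (no
    per-group retraining).  Metrics of an empty group are reported absent
    (NaN), not zero.
    """
    g = np.asarray(gold, dtype=int)
    rows = []
    for name, idx in zip(group_names, groups):
        for method, pred in predictions.items():
            pred = np.asarray(pred, dtype=int)
            if len(idx) == 0:
                p = r = f = float("nan")
            else:
                p, r, f = precision_recall_f(confusion(g[idx], pred[idx]))
            rows.append(
                {
                    "group": name,
                    "size": int(len(idx)),
                    "method": method,
                    "precision": p,
                    "recall": r,
                    "f_measure": f,
                }
            )
    return pd.DataFrame(rows)
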