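"""Integration of the machine-learning and rule-based decisions.

Two strategies:

* **union** (the MRIM strategy): a post is useless only when *both*
  component methods call it useless -- logically, the integrated label is
  the OR of the two labels.  Motivated by never missing rescue-relevant
  content: the union's recall is at least each component's recall, at the
  price of pooling their false positives.
* **weighted score**: Integrated_Score = (1 - w) * SVM_Score +
  w * Rule_Based_Score, useful iff the score >= 40 (inclusive), with w
  swept over [0, 1].  w = 0 reproduces the SVM alone and w = 1 the rule
  method alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import confusion, precision_recall_f

__all__ = [
    "IntegrationConfig",
    "integrate_union",
    "integrate_union_many",
    "integrate_weighted",
    "integrate_weighted_many",
    "sweep_weight",
]


@dataclass(frozen=True)
class IntegrationConfig:
    w: float = 0.51
    threshold: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")


def integrate_union(svm_label: int, rule_label: int) -> int:
    """Useful iff either method says useful (logical OR)."""
    if svm_label not in (0, 1) or rule_label not in (0, 1):
        raise ValueError("labels must be 0 or 1")
    return int(svm_label or rule_label)


def integrate_union_many(
    svm_labels: Sequence[int], rule_labels: Sequence[int]
) -> np.ndarray:
    s = np.asarray(svm_labels, dtype=int)
    r = np.asarray(rule_labels, dtype=int)
    if s.shape != r.shape:
        raise ValueError("label vectors differ in length")
    if not (np.isin(s, (0, 1)).all() and np.isin(r, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    return (s | r).astype(int)


def integrate_weighted(
    svm_score: float, rule_score: float, config: IntegrationConfig
) -> tuple[float, int]:
    """(Integrated_Score, label) for one post."""
    if svm_score not in (0, 100):
        raise ValueError("SVM_Score must be 0 or 100")
    if rule_score < 0:
        raise ValueError("Rule_Based_Score must be >= 0")
    score = (1.0 - config.w) * svm_score + config.w * rule_score
    return score, int(score >= config.threshold)


def integrate_weighted_many(
    svm_scores: Sequence[float], rule_scores: Sequence[float], config: IntegrationConfig
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(svm_scores, dtype=float)
    r = np.asarray(rule_scores, dtype=float)
    scores = (1.0 - config.w) * s + config.w * r
    return scores, (scores >= config.threshold).astype(int)


def sweep_weight(
    gold: Sequence[int],
    svm_scores: Sequence[float],
    rule_scores: Sequence[float],
    grid: Sequence[float] | None = None,
    threshold: float = 40.0,
) -> tuple[pd.DataFrame, float]:
    """F-measure of the weighted integration across a grid of w values.

    Returns (table with columns w/precision/recall/f_measure, argmax-F w;
    ties resolved toward the smaller w).  Default grid is step 0.01 over
    [0, 1].
    """
    if grid is None:
        grid = np.round(np.linspace(0.0, 1.0, 101), 2)
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("weight grid must be non-empty")
    g = np.asarray(gold, dtype=int)
    rows = []
    for w in grid:
        _, pred = integrate_weighted_many(
            svm_scores, rule_scores, IntegrationConfig(w=float(w), threshold=threshold)
        )
        p, r, f = precision_recall_f(confusion(g, pred))
        rows.append({"w": float(w), "precision": p, "recall": r, "f_measure": f})
    table = pd.DataFrame(rows)
    best_w = float(table.loc[table["f_measure"].idxmax(), "w"])
    return table, best_w
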