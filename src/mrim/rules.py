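"""Expert-weighted rule scorer for microblog usefulness.

Six judgment dimensions, elicited from emergency-management experts, score
a post on a 0-100 scale:

======  ========================  ======  =============================================
dim     meaning                   weight  value
======  ========================  ======  =============================================
A1      attention score           0.20    likes/10 + comments/10 + shares/10 (each
                                          parameter capped at 33.3)
A2      user score                0.10    prior_posts/100 + followers/100 + fans/100
                                          (each capped at 33.3)
A3      emotional score           0.05    |sentiment value| capped at 100
A4      text word score           0.05    word count capped at 100
A5      exact address score       0.20    100 if an exact address is present else 0
A6      contact score             0.40    100 if contact information is present else 0
======  ========================  ======  =============================================

The total is the weighted sum; a post is useful iff total >= the boundary
score (default 40, inclusive).  Per-parameter caps guard against extreme
engagement values distorting the total; they were chosen on the study
corpus to exceed ~90% of observed values and ship here as fixed defaults,
with :func:`percentile_caps` available to recompute them for a new corpus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .corpus import COUNT_FIELDS, Corpus, Microblog
from .features import FeatureRecord

__all__ = [
    "DEFAULT_RULE_CONFIG",
    "DimensionScores",
    "RuleConfig",
    "dimension_scores",
    "classify_post",
    "parameter_score",
    "percentile_caps",
    "rule_classify",
    "score_corpus",
    "usefulness_score",
]

DIMENSIONS = ("a1", "a2", "a3", "a4", "a5", "a6")

_DEFAULT_WEIGHTS = {"a1": 0.20, "a2": 0.10, "a3": 0.05, "a4": 0.05, "a5": 0.20, "a6": 0.40}
_DEFAULT_DIVISORS = {
    "likes": 10.0,
    "comments": 10.0,
    "shares": 10.0,
    "prior_posts": 100.0,
    "followers": 100.0,
    "fans": 100.0,
}
# the printed caps are the literal 33.3, not 100/3
_DEFAULT_CAPS = {name: 33.3 for name in COUNT_FIELDS}
_DEFAULT_CAPS.update({"sentiment": 100.0, "word_count": 100.0, "address": 100.0, "contact": 100.0})


@dataclass(frozen=True)
class RuleConfig:
    """Weights, divisors, caps and boundary score of the rule scorer."""

    weights: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    divisors: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DIVISORS))
    caps: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_CAPS))
    threshold: float = 40.0
    #: "absolute" scores |sentiment| (both polarities matter for rescue
    #: relevance); "positive_only" scores max(sentiment, 0).
    emotion_mode: str = "absolute"

    def __post_init__(self) -> None:
        if sorted(self.weights) != sorted(DIMENSIONS):
            raise ValueError(f"weights must cover exactly {DIMENSIONS}")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("dimension weights must sum to 1")
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("weights must lie in [0, 1]")
        if sorted(self.divisors) != sorted(COUNT_FIELDS):
            raise ValueError(f"divisors must cover exactly {COUNT_FIELDS}")
        if any(d <= 0 for d in self.divisors.values()):
            raise ValueError("divisors must be positive")
        if any(c <= 0 for c in self.caps.values()):
            raise ValueError("caps must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.emotion_mode not in ("absolute", "positive_only"):
            raise ValueError("emotion_mode must be 'absolute' or 'positive_only'")

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": dict(self.weights),
                    "divisors": dict(self.divisors),
                    "caps": dict(self.caps),
                    "threshold": self.threshold,
                    "emotion_mode": self.emotion_mode,
                },
                indent=2,
                sort_keys=True,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RuleConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


DEFAULT_RULE_CONFIG = RuleConfig()


@dataclass(frozen=True)
class DimensionScores:
    """A post's six dimension scores and their weighted total."""

    a1_attention: float
    a2_user: float
    a3_emotion: float
    a4_words: float
    a5_address: float
    a6_contact: float
    total: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.a1_attention,
            self.a2_user,
            self.a3_emotion,
            self.a4_words,
            self.a5_address,
            self.a6_contact,
        )


def parameter_score(raw: float, divisor: float, cap: float) -> float:
    """min(raw / divisor, cap); raw must be non-negative."""
    if raw < 0:
        raise ValueError(f"raw parameter value must be >= 0, got {raw}")
    if divisor <= 0 or cap <= 0:
        raise ValueError("divisor and cap must be positive")
    return min(raw / divisor, cap)


def dimension_scores(
    features: FeatureRecord, post: Microblog, config: RuleConfig = DEFAULT_RULE_CONFIG
) -> DimensionScores:
    """Score the six dimensions of one post.

    A dimension's value is the SUM of its parameter scores (three capped
    parameters each for attention and user, so A1, A2 max out at 99.9).
    """
    a1 = sum(
        parameter_score(getattr(post, name), config.divisors[name], config.caps[name])
        for name in ("likes", "comments", "shares")
    )
    a2 = sum(
        parameter_score(getattr(post, name), config.divisors[name], config.caps[name])
        for name in ("prior_posts", "followers", "fans")
    )
    if config.emotion_mode == "absolute":
        emotion_raw = abs(features.sentiment_value)
    else:
        emotion_raw = max(features.sentiment_value, 0.0)
    a3 = min(emotion_raw, config.caps["sentiment"])
    a4 = min(float(features.word_count), config.caps["word_count"])
    a5 = config.caps["address"] * features.has_exact_address
    a6 = config.caps["contact"] * features.has_contact
    dims = (a1, a2, a3, a4, a5, a6)
    total = math.fsum(config.weights[d] * v for d, v in zip(DIMENSIONS, dims))
    return DimensionScores(*dims, total=total)


def usefulness_score(dims: DimensionScores, config: RuleConfig = DEFAULT_RULE_CONFIG) -> float:
    """Weighted total over the six dimensions (the Rule_Based_Score)."""
    return math.fsum(config.weights[d] * v for d, v in zip(DIMENSIONS, dims.as_tuple()))


def rule_classify(score: float, threshold: float = 40.0) -> tuple[int, float]:
    """(label, score): useful (1) iff score >= threshold (boundary inclusive)."""
    return (1 if score >= threshold else 0), score


def classify_post(
    post: Microblog, features: FeatureRecord, config: RuleConfig = DEFAULT_RULE_CONFIG
) -> tuple[int, float, DimensionScores]:
    """Convenience composition: dimensions -> total -> decision."""
    dims = dimension_scores(features, post, config)
    label, score = rule_classify(dims.total, config.threshold)
    return label, score, dims


def score_corpus(corpus: Corpus, features_frame, config: RuleConfig = DEFAULT_RULE_CONFIG):
    """Rule scores for a whole corpus given its feature table.

    Returns a DataFrame keyed by id with the six dimension scores, the
    total and the rule label.
    """
    import pandas as pd

    rows = []
    for post in corpus:
        f = features_frame.loc[post.id]
        feat = FeatureRecord(
            word_count=int(f["word_count"]),
            sentiment_value=float(f["sentiment_value"]),
            has_exact_address=int(f["has_exact_address"]),
            has_contact=int(f["has_contact"]),
            matched_address_level=(
                int(f["matched_address_level"])
                if f["has_exact_address"] and not pd.isna(f["matched_address_level"])
                else None
            ),
        )
        label, score, dims = classify_post(post, feat, config)
        rows.append(
            {
                "id": post.id,
                "a1_attention": dims.a1_attention,
                "a2_user": dims.a2_user,
                "a3_emotion": dims.a3_emotion,
                "a4_words": dims.a4_words,
                "a5_address": dims.a5_address,
                "a6_contact": dims.a6_contact,
                "rule_score": score,
                "rule_label": label,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def percentile_caps(corpus: Corpus, q: float = 0.90) -> dict[str, float]:
    """Recompute count-parameter caps as the q-quantile of raw/divisor values.

    Optional helper for adapting the scorer to a new corpus; the shipped
    defaults are the fixed study-corpus caps.
    """
    import numpy as np

    caps = {}
    cfg = DEFAULT_RULE_CONFIG
    for name in COUNT_FIELDS:
        vals = np.array([getattr(p, name) for p in corpus], dtype=float) / cfg.divisors[name]
        cap = float(np.quantile(vals, q))
        caps[name] = cap if cap > 0 else cfg.caps[name]
    return caps
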