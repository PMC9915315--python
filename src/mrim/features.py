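"""Content features of a microblog.

Four features feed the rule scorer and the grouped analyses:

* ``word_count`` -- tokens left after markup stripping, dictionary
  segmentation and stop-word removal;
* ``sentiment_value`` -- a lexicon-weighted signed sum.  The token list is
  traversed left to right; each emotional word (polarity +-1) contributes
  its polarity times the product of degree-adverb multipliers seen since
  the previous emotional word, with the sign flipped once per negation
  word in that same window (``(-1)**k``);
* ``has_exact_address`` -- 1 iff some span ends with an address
  feature-word suffix (levels 1-5) preceded by at least ``min_prefix``
  plausible name characters;
* ``has_contact`` -- 1 iff a contact pattern (mainland-Chinese mobile or
  landline number, or contact keyword + digit run) matches.

Modifier scope follows the standard lexicon-method convention: degree
adverbs and negations apply to the *next* emotional word only.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import Microblog
from .lexicons import AddressLexicon, SentimentLexicon, TokenizerResources

__all__ = [
    "AddressMatch",
    "DEFAULT_CONTACT_PATTERNS",
    "DEFAULT_MARKUP_PATTERNS",
    "ExtractionResources",
    "FeatureRecord",
    "detect_contact",
    "detect_exact_address",
    "extract_features",
    "extract_features_frame",
    "sentiment_polarity",
    "sentiment_value",
    "strip_markup",
    "tokenize",
    "word_count",
]

#: Removed in order by :func:`strip_markup`: closed/unclosed angle-bracket
#: tags, embedded hyperlinks, and topic-hashtag delimiters (the ``#``
#: characters are removed, the words inside a topic are kept).
DEFAULT_MARKUP_PATTERNS: tuple[str, ...] = (
    r"<[^<>]*>",          # well-formed tags
    r"<[^<>]*$",          # unclosed trailing tag
    r"https?://\S+",      # embedded hyperlinks
    r"#",                 # topic-hashtag delimiters
)

#: Default contact patterns: 11-digit mobile (1 then 3-9), landline with
#: 3-4 digit area code, and an explicit contact keyword next to a digit run.
DEFAULT_CONTACT_PATTERNS: tuple[re.Pattern[str], ...] = (
    re.compile(r"(?<!\d)1[3-9]\d{9}(?!\d)"),
    re.compile(r"(?<!\d)0\d{2,3}[-\s]\d{7,8}(?!\d)"),
    re.compile(r"(?:联系|电话|手机|contact|tel)\D{0,3}\d{5,}", re.IGNORECASE),
)


def strip_markup(text: str, patterns: Sequence[str] = DEFAULT_MARKUP_PATTERNS) -> str:
    """Remove markup tags and platform artifacts, preserving visible text.

    Idempotent; an empty input yields an empty output.
    """
    for pat in patterns:
        text = re.sub(pat, " ", text)
    # collapse the whitespace that replacement introduced
    return re.sub(r"[ \t]+", " ", text).strip()


def tokenize(text: str, resources: TokenizerResources) -> list[str]:
    """Segment plain text into an ordered token list.

    Whitespace-delimited chunks are split first; inside a chunk the
    strategy is greedy longest match against the dictionary, then a
    maximal ASCII digit run as a single token (so phone numbers survive as
    one token, as mainstream Chinese segmenters do), then a single
    character.  Concatenating the tokens reproduces the input minus
    whitespace.  The tokenizer is deterministic; swap in any callable with
    the same contract for other segmentation strategies.
    """
    tokens: list[str] = []
    dictionary = resources.dictionary
    max_len = resources.max_word_len
    for chunk in text.split():
        i = 0
        n = len(chunk)
        while i < n:
            match_len = 0
            for length in range(min(max_len, n - i), 0, -1):
                if chunk[i : i + length] in dictionary:
                    match_len = length
                    break
            if match_len:
                tokens.append(chunk[i : i + match_len])
                i += match_len
            elif chunk[i].isdigit() and chunk[i].isascii():
                j = i + 1
                while j < n and chunk[j].isdigit() and chunk[j].isascii():
                    j += 1
                tokens.append(chunk[i:j])
                i = j
            else:
                tokens.append(chunk[i])
                i += 1
    return tokens


def word_count(text: str, resources: TokenizerResources) -> int:
    """Number of tokens after markup stripping and stop-word removal."""
    tokens = tokenize(strip_markup(text), resources)
    stop = resources.stop_words
    return sum(1 for t in tokens if t not in stop)


def sentiment_value(tokens: Iterable[str], lexicon: SentimentLexicon) -> float:
    """Signed lexicon sum over a token list (see module docstring for the rule)."""
    total = 0.0
    multiplier = 1.0
    negations = 0
    emotional = lexicon.emotional_words
    degree = lexicon.degree_adverbs
    negation = lexicon.negation_words
    for tok in tokens:
        if tok in emotional:
            total += emotional[tok] * multiplier * ((-1.0) ** negations)
            multiplier = 1.0
            negations = 0
        elif tok in degree:
            multiplier *= degree[tok]
        elif tok in negation:
            negations += 1
    return total


def sentiment_polarity(value: float) -> str:
    """Map a sentiment value to ``positive`` / ``negative`` / ``neutral``."""
    if value > 0:
        return "positive"
    if value < 0:
        return "negative"
    return "neutral"


@dataclass(frozen=True)
class AddressMatch:
    flag: int
    level: int | None
    span: str | None


def _is_name_char(ch: str, stop_words: frozenset[str]) -> bool:
    if ch.isspace() or ch in stop_words:
        return False
    cat = unicodedata.category(ch)
    return not cat.startswith("P") and not cat.startswith("S")


def detect_exact_address(
    text: str,
    lexicon: AddressLexicon,
    *,
    stop_words: frozenset[str] = frozenset(),
    min_prefix: int = 2,
    ner_hook=None,
) -> AddressMatch:
    """Flag an exact address: a feature-word suffix with a plausible name before it.

    A candidate fires when a suffix from any level 1-5 is preceded by at
    least ``min_prefix`` consecutive non-stop-word, non-punctuation
    characters (suppressing bare suffixes).  The highest-specificity
    (largest level) match is reported; ties go to the leftmost occurrence.
    ``ner_hook``, if given, is called as ``ner_hook(text)`` and may return
    an :class:`AddressMatch` that overrides a non-match (pluggable named
    entity recognition; disabled by default).
    """
    for level in range(5, 0, -1):
        best_start: int | None = None
        best_end = -1
        for suffix in lexicon.levels[level]:
            start = 0
            while True:
                idx = text.find(suffix, start)
                if idx < 0:
                    break
                prefix = text[idx - min_prefix : idx]
                if len(prefix) == min_prefix and all(
                    _is_name_char(c, stop_words) for c in prefix
                ):
                    span_start = idx - min_prefix
                    span_end = idx + len(suffix)
                    # leftmost occurrence wins; at equal start, the longer span
                    if (
                        best_start is None
                        or span_start < best_start
                        or (span_start == best_start and span_end > best_end)
                    ):
                        best_start, best_end = span_start, span_end
                start = idx + 1
        if best_start is not None:
            return AddressMatch(1, level, text[best_start:best_end])
    if ner_hook is not None:
        hooked = ner_hook(text)
        if hooked is not None and hooked.flag:
            return hooked
    return AddressMatch(0, None, None)


def detect_contact(
    text: str, patterns: Sequence[re.Pattern[str]] = DEFAULT_CONTACT_PATTERNS
) -> int:
    """1 iff any configured contact pattern matches the plain text."""
    return int(any(p.search(text) for p in patterns))


@dataclass(frozen=True)
class FeatureRecord:
    """Per-post derived content features."""

    word_count: int
    sentiment_value: float
    has_exact_address: int
    has_contact: int
    matched_address_level: int | None = None
    matched_address_span: str | None = None

    def __post_init__(self) -> None:
        if self.word_count < 0:
            raise ValueError("word_count must be >= 0")
        if self.has_exact_address not in (0, 1) or self.has_contact not in (0, 1):
            raise ValueError("flags must be 0 or 1")
        if (self.matched_address_level is not None) != bool(self.has_exact_address):
            raise ValueError("matched_address_level present iff has_exact_address == 1")


@dataclass(frozen=True)
class ExtractionResources:
    """Bundle of everything :func:`extract_features` needs."""

    sentiment: SentimentLexicon
    address: AddressLexicon
    tokenizer: TokenizerResources
    contact_patterns: tuple[re.Pattern[str], ...] = DEFAULT_CONTACT_PATTERNS
    markup_patterns: tuple[str, ...] = DEFAULT_MARKUP_PATTERNS
    min_prefix: int = 2


def extract_features(post: Microblog | str, resources: ExtractionResources) -> FeatureRecord:
    """Compose the four content features from one post's raw text.

    Total function: never raises on ordinary text, and idempotent with
    respect to repeated markup stripping.
    """
    raw = post.text if isinstance(post, Microblog) else post
    plain = strip_markup(raw, resources.markup_patterns)
    tokens = tokenize(plain, resources.tokenizer)
    stop = resources.tokenizer.stop_words
    wc = sum(1 for t in tokens if t not in stop)
    senti = sentiment_value(tokens, resources.sentiment)
    addr = detect_exact_address(
        plain,
        resources.address,
        stop_words=resources.tokenizer.stop_words,
        min_prefix=resources.min_prefix,
    )
    contact = detect_contact(plain, resources.contact_patterns)
    return FeatureRecord(
        word_count=wc,
        sentiment_value=senti,
        has_exact_address=addr.flag,
        has_contact=contact,
        matched_address_level=addr.level,
        matched_address_span=addr.span,
    )


def extract_features_frame(corpus, resources: ExtractionResources):
    """Feature table (one row per post, keyed by id) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for post in corpus:
        f = extract_features(post, resources)
        rows.append(
            {
                "id": post.id,
                "word_count": f.word_count,
                "sentiment_value": f.sentiment_value,
                "has_exact_address": f.has_exact_address,
                "has_contact": f.has_contact,
                "matched_address_level": f.matched_address_level,
            }
        )
    return pd.DataFrame(rows).set_index("id")
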