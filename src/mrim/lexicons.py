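"""Lexicon resources for feature extraction.

Three plain-text, human-editable resource families drive the content
features:

* a sentiment lexicon -- emotional words with polarity +1/-1, degree
  adverbs with positive multipliers, and negation words;
* an address lexicon -- five levels of Chinese address feature-word
  suffixes, from township/street level (1) down to detailed unit level
  (5), used to flag "exact addresses";
* tokenizer resources -- a dictionary of known multi-character words for
  greedy longest-match segmentation and a stop-word list.

The package does not redistribute the large third-party sentiment
dictionaries used in production systems; :func:`mrim.synth.generate_lexicons`
builds a small self-consistent fixture set, and any directory of files in
the formats below can be swapped in.

File formats (all UTF-8): two-column TSV ``word<TAB>value`` for emotional
words and degree adverbs; one word per line for negation words, stop words
and the dictionary; ``level<TAB>suffix`` TSV for the address lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AddressLexicon",
    "DEFAULT_ADDRESS_SUFFIXES",
    "SentimentLexicon",
    "TokenizerResources",
    "load_lexicon_dir",
    "write_lexicon_dir",
]

#: Standard Chinese address feature-word suffixes by specificity level,
#: 1 = township/street ... 5 = detailed unit.  Each suffix is assigned to
#: exactly one level (the field inventories overlap across levels; the
#: most common assignment is kept).
DEFAULT_ADDRESS_SUFFIXES: dict[int, tuple[str, ...]] = {
    1: ("镇", "乡", "办事处", "居委会", "社区", "街道"),
    2: ("村", "路", "街", "桥", "庄", "口", "店", "岛", "胡同"),
    3: ("医院", "大厦", "广场", "饭店", "中心", "大楼", "酒店", "宾馆",
        "市场", "大学", "厂", "宿舍", "花园"),
    4: ("小区", "公寓", "号院", "巷", "村委会", "坡"),
    5: ("单元", "室", "栋", "号楼", "幢", "座", "层"),
}


@dataclass(frozen=True)
class SentimentLexicon:
    """Emotional words (polarity +-1), degree adverbs (multiplier), negations."""

    emotional_words: Mapping[str, int]
    degree_adverbs: Mapping[str, float]
    negation_words: frozenset[str]

    def __post_init__(self) -> None:
        for w, p in self.emotional_words.items():
            if p not in (1, -1):
                raise ValueError(f"polarity of {w!r} must be +1 or -1, got {p}")
        for w, m in self.degree_adverbs.items():
            if not m > 0:
                raise ValueError(f"degree multiplier of {w!r} must be > 0, got {m}")
        if "" in self.emotional_words or "" in self.degree_adverbs or "" in self.negation_words:
            raise ValueError("lexicon entries must be non-empty strings")


@dataclass(frozen=True)
class AddressLexicon:
    """Feature-word suffixes per address level 1-5."""

    levels: Mapping[int, tuple[str, ...]]

    def __post_init__(self) -> None:
        if sorted(self.levels) != [1, 2, 3, 4, 5]:
            raise ValueError("address lexicon must define exactly levels 1..5")
        seen: dict[str, int] = {}
        for lvl, suffixes in self.levels.items():
            if not suffixes:
                raise ValueError(f"level {lvl} has no feature words")
            for s in suffixes:
                if not s:
                    raise ValueError("empty feature-word suffix")
                if s in seen:
                    raise ValueError(
                        f"suffix {s!r} assigned to both level {seen[s]} and level {lvl}"
                    )
                seen[s] = lvl

    @cached_property
    def suffix_to_level(self) -> dict[str, int]:
        return {s: lvl for lvl, sfx in self.levels.items() for s in sfx}

    @classmethod
    def default(cls) -> "AddressLexicon":
        return cls(levels=dict(DEFAULT_ADDRESS_SUFFIXES))


@dataclass(frozen=True)
class TokenizerResources:
    """Dictionary for longest-match segmentation plus a stop-word list."""

    dictionary: frozenset[str] = field(default_factory=frozenset)
    stop_words: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if "" in self.dictionary or "" in self.stop_words:
            raise ValueError("dictionary/stop words must be non-empty strings")

    @cached_property
    def max_word_len(self) -> int:
        return max((len(w) for w in self.dictionary), default=1)


def _read_pairs(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, _, value = line.partition("\t")
        out[word.strip()] = value.strip()
    return out


def _read_words(path: Path) -> frozenset[str]:
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def load_lexicon_dir(
    directory: str | Path,
) -> tuple[SentimentLexicon, AddressLexicon, TokenizerResources]:
    """Load the full resource set from a directory of plain-text files.

    Expects ``emotional_words.tsv``, ``degree_adverbs.tsv``,
    ``negation_words.txt``, ``stop_words.txt``, ``dictionary.txt`` and
    ``address_feature_words.tsv``.
    """
    d = Path(directory)
    sentiment = SentimentLexicon(
        emotional_words={w: int(v) for w, v in _read_pairs(d / "emotional_words.tsv").items()},
        degree_adverbs={w: float(v) for w, v in _read_pairs(d / "degree_adverbs.tsv").items()},
        negation_words=_read_words(d / "negation_words.txt"),
    )
    levels: dict[int, list[str]] = {i: [] for i in range(1, 6)}
    for line in (d / "address_feature_words.tsv").read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lvl, _, suffix = line.partition("\t")
        levels[int(lvl)].append(suffix.strip())
    address = AddressLexicon(levels={k: tuple(v) for k, v in levels.items()})
    tokenizer = TokenizerResources(
        dictionary=_read_words(d / "dictionary.txt"),
        stop_words=_read_words(d / "stop_words.txt"),
    )
    return sentiment, address, tokenizer


def write_lexicon_dir(
    directory: str | Path,
    sentiment: SentimentLexicon,
    address: AddressLexicon,
    tokenizer: TokenizerResources,
) -> None:
    """Write the resource set in the formats read by :func:`load_lexicon_dir`."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def _pairs(path: Path, items: Iterable[tuple[str, object]]) -> None:
        path.write_text(
            "".join(f"{w}\t{v}\n" for w, v in sorted(items)), encoding="utf-8"
        )

    def _words(path: Path, words: Iterable[str]) -> None:
        path.write_text("".join(f"{w}\n" for w in sorted(words)), encoding="utf-8")

    _pairs(d / "emotional_words.tsv", sentiment.emotional_words.items())
    _pairs(d / "degree_adverbs.tsv", sentiment.degree_adverbs.items())
    _words(d / "negation_words.txt", sentiment.negation_words)
    _words(d / "stop_words.txt", tokenizer.stop_words)
    _words(d / "dictionary.txt", tokenizer.dictionary)
    with (d / "address_feature_words.tsv").open("w", encoding="utf-8") as fh:
        for lvl in range(1, 6):
            for suffix in address.levels[lvl]:
                fh.write(f"{lvl}\t{suffix}\n")
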