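"""Microblog records and corpus containers.

A microblog is one short social-media post produced during an emergency:
raw text (markup intact -- all cleaning happens downstream) plus six
non-negative engagement/author counts and an optional binary usefulness
label (1 = useful for rescue operations, 0 = useless).  Corpora are read
and written in two interchange forms: a UTF-8 delimited (CSV) file with a
header row, and a record-per-line (JSON lines) file.  An absent label is
an empty field, never zero: unlabeled corpora must stay classifiable
without fabricating gold labels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

__all__ = [
    "COUNT_FIELDS",
    "FIELD_ORDER",
    "Corpus",
    "Microblog",
    "RecordValidationError",
    "SchemaError",
    "read_corpus",
    "validate_record",
    "write_corpus",
]

#: The six numeric metadata fields carried by every post, in canonical order:
#: three communication (attention) counts and three author (user) counts.
COUNT_FIELDS = ("likes", "comments", "shares", "prior_posts", "followers", "fans")
FIELD_ORDER = ("id", "text") + COUNT_FIELDS + ("label",)


class RecordValidationError(ValueError):
    """A single record violates the Microblog invariants.

    Carries the offending field name and, when raised during file
    reading, the zero-based row index.
    """

    def __init__(self, message: str, *, field_name: str | None = None, row: int | None = None):
        super().__init__(message)
        self.field_name = field_name
        self.row = row


class SchemaError(ValueError):
    """The file's columns/keys do not match the Microblog schema."""


@dataclass(frozen=True)
class Microblog:
    """One post: raw text, engagement counts, optional gold label."""

    id: str
    text: str
    likes: int
    comments: int
    shares: int
    prior_posts: int
    followers: int
    fans: int
    label: int | None = None

    def as_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name) for name in FIELD_ORDER}


def _coerce_count(name: str, value: Any, row: int | None = None) -> int:
    try:
        if isinstance(value, float) and not value.is_integer():
            raise ValueError
        out = int(str(value).strip()) if not isinstance(value, (int, float)) else int(value)
    except (TypeError, ValueError):
        raise RecordValidationError(
            f"field {name!r} must be a non-negative integer, got {value!r}",
            field_name=name,
            row=row,
        ) from None
    if out < 0:
        raise RecordValidationError(
            f"field {name!r} must be >= 0, got {out}", field_name=name, row=row
        )
    return out


def validate_record(raw: Mapping[str, Any], *, row: int | None = None) -> Microblog:
    """Validate a field map and return a :class:`Microblog`.

    Raises :class:`RecordValidationError` naming the offending field for a
    negative or non-integer count, a non-binary label, or missing text.
    """
    missing = [k for k in ("id", "text") + COUNT_FIELDS if k not in raw or raw[k] is None]
    # text may legitimately be empty, but the key must exist
    if missing:
        raise RecordValidationError(
            f"missing required field(s): {', '.join(missing)}",
            field_name=missing[0],
            row=row,
        )
    counts = {name: _coerce_count(name, raw[name], row) for name in COUNT_FIELDS}
    label_raw = raw.get("label")
    label: int | None
    if label_raw is None or (isinstance(label_raw, str) and label_raw.strip() == ""):
        label = None
    else:
        try:
            label = int(str(label_raw).strip())
        except (TypeError, ValueError):
            raise RecordValidationError(
                f"label must be 0 or 1, got {label_raw!r}", field_name="label", row=row
            ) from None
        if label not in (0, 1):
            raise RecordValidationError(
                f"label must be 0 or 1, got {label}", field_name="label", row=row
            )
    return Microblog(id=str(raw["id"]), text=str(raw["text"]), label=label, **counts)


@dataclass
class Corpus:
    """An ordered sequence of unique-id microblogs plus free-text provenance."""

    records: list[Microblog] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise RecordValidationError(
                    f"duplicate record id {rec.id!r}", field_name="id"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Microblog]:
        return iter(self.records)

    def __getitem__(self, i: int) -> Microblog:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> list[int | None]:
        return [r.label for r in self.records]

    def texts(self) -> list[str]:
        return [r.text for r in self.records]

    def with_labels(self, labels: Iterable[int]) -> "Corpus":
        labels = list(labels)
        if len(labels) != len(self.records):
            raise ValueError("label vector length does not match corpus size")
        return Corpus(
            records=[replace(r, label=int(l)) for r, l in zip(self.records, labels)],
            provenance=dict(self.provenance),
        )


def _serialize(rec: Microblog) -> dict[str, Any]:
    d = rec.as_dict()
    if d["label"] is None:
        d["label"] = ""
    return d


def write_corpus(corpus: Corpus, path: str | Path, format: str = "delimited") -> None:
    """Write a corpus losslessly; ``read_corpus`` round-trips it field-for-field.

    ``delimited`` is UTF-8 CSV with a header row and a quoted text field;
    ``record_per_line`` is one JSON object per line with the same keys.
    Absent labels are written as empty fields (CSV) or nulls (JSON lines).
    """
    path = Path(path)
    if format == "delimited":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=FIELD_ORDER)
            writer.writeheader()
            for rec in corpus:
                writer.writerow(_serialize(rec))
    elif format == "record_per_line":
        with path.open("w", encoding="utf-8") as fh:
            for rec in corpus:
                d = rec.as_dict()
                fh.write(json.dumps(d, ensure_ascii=False, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def read_corpus(
    path: str | Path,
    format: str = "delimited",
    *,
    on_error: str = "raise",
) -> Corpus:
    """Read a corpus file, validating every row.

    With ``on_error='raise'`` (default) the first malformed row aborts the
    read with a :class:`RecordValidationError` citing the row index.  With
    ``on_error='skip'`` malformed rows are dropped and accounted for in
    ``provenance['skipped_rows']`` (a list of ``(row_index, message)``)
    and ``provenance['n_skipped']`` -- a row is never dropped silently.
    A missing column raises :class:`SchemaError` naming the column.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    path = Path(path)
    records: list[Microblog] = []
    skipped: list[tuple[int, str]] = []

    def _handle(idx: int, exc: RecordValidationError) -> None:
        if on_error == "raise":
            raise exc
        skipped.append((idx, str(exc)))

    if format == "delimited":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in FIELD_ORDER if c not in header]
            if missing:
                raise SchemaError(f"missing required column(s): {', '.join(missing)}")
            for idx, row in enumerate(reader):
                try:
                    records.append(validate_record(row, row=idx))
                except RecordValidationError as exc:
                    _handle(idx, exc)
    elif format == "record_per_line":
        with path.open("r", encoding="utf-8") as fh:
            for idx, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    _handle(idx, RecordValidationError(f"invalid JSON: {exc}", row=idx))
                    continue
                if not isinstance(obj, dict):
                    _handle(idx, RecordValidationError("record is not an object", row=idx))
                    continue
                missing = [c for c in ("id", "text") + COUNT_FIELDS if c not in obj]
                if missing:
                    _handle(
                        idx,
                        RecordValidationError(
                            f"missing required field(s): {', '.join(missing)}",
                            field_name=missing[0],
                            row=idx,
                        ),
                    )
                    continue
                try:
                    records.append(validate_record(obj, row=idx))
                except RecordValidationError as exc:
                    _handle(idx, exc)
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    provenance: dict[str, Any] = {"source": str(path), "format": format}
    provenance["n_skipped"] = len(skipped)
    if skipped:
        provenance["skipped_rows"] = skipped
    return Corpus(records=records, provenance=provenance)
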