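"""Span-annotated corpus I/O and span <-> BIO conversion.

Clinical NER corpora in the CCKS style annotate each record as raw text plus
a list of typed character-offset entity spans, serialized one JSON object per
line.  Sequence taggers instead consume per-character BIO tags.  This module
holds the validated in-memory containers (:class:`Record`, :class:`Sentence`,
:class:`TaggedSequence`) and the lossless conversions between the two views:

* JSONL records  <->  :class:`Record` (configurable key names, since field
  names vary between corpus releases; inclusive-end offsets can be converted
  at the reader boundary);
* record -> sentences, splitting on the Chinese period while conserving every
  character (the separator stays attached to the preceding sentence);
* spans -> BIO tags and back, a strict round-trip identity.

All offsets are 0-based half-open.  Tagging is per Unicode code point, the
standard granularity for Chinese clinical text, which has no whitespace word
boundaries.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CorpusError",
    "ParseError",
    "ValidationError",
    "EntitySpan",
    "Record",
    "Sentence",
    "TaggedSequence",
    "JsonlDialect",
    "read_records",
    "write_records",
    "split_sentences",
    "spans_to_bio",
    "bio_to_spans",
    "read_bio",
    "write_bio",
]

DEFAULT_SEPARATORS = ("。",)  # Chinese full stop 。

_TAG_RE = re.compile(r"^(O|[BI]-\w+)$")


class CorpusError(Exception):
    """Base class for corpus reading/validation failures."""


class ParseError(CorpusError):
    """Malformed file content (bad JSON, wrong column count, bad tag)."""


class ValidationError(CorpusError):
    """Structurally invalid annotation (bad offsets, overlap, BIO breakage)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity mention at [start, end) in some text.

    ``surface`` is denormalized for convenience and must equal
    ``text[start:end]`` of the carrying Record/Sentence; :func:`_check_spans`
    enforces this.
    """

    start: int
    end: int
    etype: str
    surface: str

    def shifted(self, delta: int) -> "EntitySpan":
        return replace(self, start=self.start + delta, end=self.end + delta)


def _check_spans(text: str, entities: Sequence[EntitySpan], owner: str) -> None:
    prev_end = 0
    for ent in entities:
        if not (0 <= ent.start < ent.end <= len(text)):
            raise ValidationError(
                f"{owner}: span ({ent.start}, {ent.end}) out of range for "
                f"text of length {len(text)}"
            )
        if ent.start < prev_end:
            raise ValidationError(
                f"{owner}: span ({ent.start}, {ent.end}) overlaps or is out "
                f"of order with the previous span ending at {prev_end}"
            )
        if text[ent.start : ent.end] != ent.surface:
            raise ValidationError(
                f"{owner}: surface {ent.surface!r} does not match "
                f"text[{ent.start}:{ent.end}] == {text[ent.start:ent.end]!r}"
            )
        prev_end = ent.end


@dataclass(frozen=True)
class Record:
    """One clinical document: raw text plus sorted, non-overlapping spans."""

    record_id: str
    text: str
    entities: tuple[EntitySpan, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", tuple(self.entities))
        _check_spans(self.text, self.entities, f"record {self.record_id!r}")


@dataclass(frozen=True)
class Sentence:
    """A period-delimited unit of a record with re-based spans.

    ``provenance`` is ``"original"`` for sentences cut from source records
    and ``"synthesized"`` for augmentation variants, in which case
    ``substitutions`` logs every (entity index, replaced segment text,
    replacement text) applied to the parent.
    """

    text: str
    entities: tuple[EntitySpan, ...] = ()
    provenance: str = "original"
    parent_id: str = ""
    substitutions: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", tuple(self.entities))
        object.__setattr__(self, "substitutions", tuple(
            (int(i), str(s), str(r)) for i, s, r in self.substitutions
        ))
        if self.provenance not in ("original", "synthesized"):
            raise ValidationError(
                f"provenance must be 'original' or 'synthesized', "
                f"got {self.provenance!r}"
            )
        if self.provenance == "synthesized" and not self.substitutions:
            raise ValidationError(
                "a synthesized sentence must record at least one substitution"
            )
        _check_spans(self.text, self.entities, f"sentence {self.parent_id!r}")


@dataclass(frozen=True)
class TaggedSequence:
    """Parallel character and BIO tag sequences of equal length."""

    chars: tuple[str, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chars", tuple(self.chars))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.chars) != len(self.tags):
            raise ValidationError(
                f"{len(self.chars)} chars but {len(self.tags)} tags"
            )
        for ch in self.chars:
            if len(ch) != 1:
                raise ValidationError(f"chars must be single code points, got {ch!r}")
        prev = "O"
        for i, tag in enumerate(self.tags):
            if not _TAG_RE.match(tag):
                raise ParseError(f"invalid tag {tag!r} at position {i}")
            if tag.startswith("I-"):
                etype = tag[2:]
                if prev not in (f"B-{etype}", f"I-{etype}"):
                    raise ValidationError(
                        f"orphan {tag} at position {i} (previous tag {prev})"
                    )
            prev = tag

    @property
    def text(self) -> str:
        return "".join(self.chars)


# ---------------------------------------------------------------------------
# JSONL record I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JsonlDialect:
    """Key names and offset convention of a JSONL corpus release.

    Corpus releases differ in field naming and in whether the end offset is
    inclusive or exclusive; remap here instead of editing data files.
    ``span_convention`` is ``"exclusive"`` (half-open, the internal form) or
    ``"inclusive"`` (end points at the last character; converted on read and
    restored on write).
    """

    id_key: str = "id"
    text_key: str = "text"
    entities_key: str = "entities"
    start_key: str = "start"
    end_key: str = "end"
    type_key: str = "type"
    span_convention: str = "exclusive"

    def __post_init__(self) -> None:
        if self.span_convention not in ("exclusive", "inclusive"):
            raise ValueError(
                f"span_convention must be 'exclusive' or 'inclusive', "
                f"got {self.span_convention!r}"
            )


def read_records(
    path: str | Path, dialect: JsonlDialect = JsonlDialect()
) -> list[Record]:
    """Read span-annotated records from a JSONL file.

    Raises :class:`ParseError` with the 1-based line number on malformed
    JSON and :class:`ValidationError` naming the record on bad spans.
    """
    records: list[Record] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            records.append(_record_from_obj(obj, dialect, default_id=str(lineno)))
    return records


def _record_from_obj(
    obj: Mapping, dialect: JsonlDialect, default_id: str
) -> Record:
    record_id = str(obj.get(dialect.id_key, default_id))
    try:
        text = obj[dialect.text_key]
    except KeyError:
        raise ParseError(f"record {record_id!r}: missing key {dialect.text_key!r}")
    extra = 1 if dialect.span_convention == "inclusive" else 0
    entities = []
    for ent in obj.get(dialect.entities_key, []):
        start = int(ent[dialect.start_key])
        end = int(ent[dialect.end_key]) + extra
        entities.append(
            EntitySpan(start=start, end=end, etype=str(ent[dialect.type_key]),
                       surface=text[start:end])
        )
    entities.sort(key=lambda e: (e.start, e.end))
    return Record(record_id=record_id, text=text, entities=tuple(entities))


def write_records(
    records: Iterable[Record | Sentence],
    path: str | Path,
    dialect: JsonlDialect = JsonlDialect(),
) -> None:
    """Write records (or sentences) as JSONL, one object per line.

    Sentences additionally carry provenance metadata so an augmented corpus
    is self-describing.
    """
    extra = 1 if dialect.span_convention == "inclusive" else 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            ents = [
                {
                    dialect.start_key: e.start,
                    dialect.end_key: e.end - extra,
                    dialect.type_key: e.etype,
                    "surface": e.surface,
                }
                for e in rec.entities
            ]
            if isinstance(rec, Sentence):
                obj = {
                    dialect.id_key: rec.parent_id,
                    dialect.text_key: rec.text,
                    dialect.entities_key: ents,
                    "provenance": rec.provenance,
                }
                if rec.substitutions:
                    obj["substitutions"] = [list(s) for s in rec.substitutions]
            else:
                obj = {
                    dialect.id_key: rec.record_id,
                    dialect.text_key: rec.text,
                    dialect.entities_key: ents,
                }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def read_sentences(
    path: str | Path, dialect: JsonlDialect = JsonlDialect()
) -> list[Sentence]:
    """Read a JSONL file written by :func:`write_records` back as Sentences."""
    sentences = []
    for rec in read_records(path, dialect):
        sentences.append(
            Sentence(text=rec.text, entities=rec.entities, parent_id=rec.record_id)
        )
    return sentences


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------


def split_sentences(
    record: Record,
    separators: Sequence[str] = DEFAULT_SEPARATORS,
    policy: str = "error",
) -> list[Sentence]:
    """Split a record at sentence separators, re-basing entity offsets.

    The separator character stays attached to the preceding sentence so that
    the concatenation of sentence texts reproduces the record text exactly.
    An empty trailing segment after a final separator is dropped.

    An entity straddling a separator raises :class:`ValidationError` under
    ``policy="error"`` (the default; well-formed clinical annotations do not
    cross sentence boundaries) or, under ``policy="keep-record"``, suppresses
    splitting for that record, which is then returned as one sentence.
    """
    if policy not in ("error", "keep-record"):
        raise ValueError(f"unknown split policy {policy!r}")
    seps = set(separators)
    cuts = [i + 1 for i, ch in enumerate(record.text) if ch in seps]
    if not cuts or cuts[-1] != len(record.text):
        cuts.append(len(record.text))

    straddlers = [
        e for e in record.entities
        if any(e.start < c < e.end for c in cuts)
    ]
    if straddlers:
        if policy == "error":
            e = straddlers[0]
            raise ValidationError(
                f"record {record.record_id!r}: entity {e.surface!r} "
                f"({e.start}, {e.end}) crosses a sentence boundary"
            )
        return [
            Sentence(text=record.text, entities=record.entities,
                     parent_id=f"{record.record_id}#0")
        ]

    sentences: list[Sentence] = []
    begin = 0
    for idx, cut in enumerate(cuts):
        chunk = record.text[begin:cut]
        if not chunk:
            continue
        ents = tuple(
            e.shifted(-begin) for e in record.entities
            if begin <= e.start and e.end <= cut
        )
        sentences.append(
            Sentence(text=chunk, entities=ents,
                     parent_id=f"{record.record_id}#{idx}")
        )
        begin = cut
    return sentences


# ---------------------------------------------------------------------------
# Span <-> BIO conversion
# ---------------------------------------------------------------------------


def spans_to_bio(sentence: Sentence) -> TaggedSequence:
    """Project entity spans onto per-character B/I/O tags."""
    tags = ["O"] * len(sentence.text)
    for ent in sentence.entities:
        tags[ent.start] = f"B-{ent.etype}"
        for i in range(ent.start + 1, ent.end):
            tags[i] = f"I-{ent.etype}"
    return TaggedSequence(chars=tuple(sentence.text), tags=tuple(tags))


def bio_to_spans(
    seq: TaggedSequence | tuple[Sequence[str], Sequence[str]],
    strict: bool = True,
    parent_id: str = "",
) -> Sentence:
    """Recover entity spans from BIO tags; inverse of :func:`spans_to_bio`.

    With ``strict=False`` an orphan ``I-t`` tag (no preceding ``B-t``/``I-t``
    of the same type) is repaired to ``B-t`` instead of raising; this is the
    usual leniency needed when scoring raw tagger output.
    """
    if not isinstance(seq, TaggedSequence):
        chars, tags = seq
        seq = _coerce_tagged(chars, tags, strict)
    text = seq.text
    entities: list[EntitySpan] = []
    start: int | None = None
    etype = ""
    for i, tag in enumerate(seq.tags):
        if tag.startswith("B-") or (tag.startswith("I-") and
                                    (start is None or tag[2:] != etype)):
            if start is not None:
                entities.append(EntitySpan(start, i, etype, text[start:i]))
            start, etype = i, tag[2:]
        elif tag == "O":
            if start is not None:
                entities.append(EntitySpan(start, i, etype, text[start:i]))
            start = None
    if start is not None:
        entities.append(EntitySpan(start, len(text), etype, text[start:]))
    return Sentence(text=text, entities=tuple(entities), parent_id=parent_id)


def _coerce_tagged(
    chars: Sequence[str], tags: Sequence[str], strict: bool
) -> TaggedSequence:
    if strict:
        return TaggedSequence(chars=tuple(chars), tags=tuple(tags))
    repaired = list(tags)
    prev = "O"
    for i, tag in enumerate(repaired):
        if tag.startswith("I-"):
            etype = tag[2:]
            if prev not in (f"B-{etype}", f"I-{etype}"):
                repaired[i] = f"B-{etype}"
        prev = repaired[i]
    return TaggedSequence(chars=tuple(chars), tags=tuple(repaired))


# ---------------------------------------------------------------------------
# CoNLL-style BIO file I/O
# ---------------------------------------------------------------------------


def write_bio(sequences: Iterable[TaggedSequence], path: str | Path) -> None:
    """Write two-column ``<char>\\t<tag>`` lines, blank line between sentences."""
    with open(path, "w", encoding="utf-8") as fh:
        first = True
        for seq in sequences:
            if not first:
                fh.write("\n")
            first = False
            for ch, tag in zip(seq.chars, seq.tags):
                fh.write(f"{ch}\t{tag}\n")


def read_bio(path: str | Path, strict: bool = True) -> list[TaggedSequence]:
    """Read a two-column BIO file; inverse of :func:`write_bio`."""
    sequences: list[TaggedSequence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if chars:
            sequences.append(_coerce_tagged(chars, tags, strict))
            chars.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                flush()
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
            ch, tag = cols
            if not _TAG_RE.match(tag):
                raise ParseError(f"{path}:{lineno}: invalid tag {tag!r}")
            chars.append(ch)
            tags.append(tag)
    flush()
    return sequences
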