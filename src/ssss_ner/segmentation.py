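"""Deterministic lexical segmentation of entity mentions.

Chinese clinical entity mentions are compounds of shorter "simple words"
(盆腔MRI = 盆腔 + MRI); augmentation substitutes synonyms at the simple-word
level, so the first step is cutting a mention into such words.  The built-in
segmenter is forward maximum matching (FMM) against a word lexicon: greedy
left-to-right, longest dictionary word first, falling back to one segment
per code point for out-of-lexicon runs.  FMM needs no statistical model, so
the same (text, lexicon) always yields the same cut — a pure function, which
keeps augmented corpora reproducible.

Runs of ASCII letters or of digits (with an optional decimal point) are
treated as atomic tokens before matching, so "MRI" and "3.5" never get cut
into single characters.

Production pipelines that prefer a statistical segmenter (jieba etc.) plug
it in through :func:`register_segmenter`, which enforces the one contract
every segmenter must satisfy: the segments concatenate back to the input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

__all__ = [
    "Segment",
    "SegmenterContractError",
    "Segmenter",
    "FmmSegmenter",
    "segment",
    "register_segmenter",
    "read_word_list",
]

_ATOMIC_RE = re.compile(r"[A-Za-z]+|\d+(?:\.\d+)?")


class SegmenterContractError(Exception):
    """An adapter's output does not concatenate back to its input."""


@dataclass(frozen=True)
class Segment:
    """A contiguous piece of the segmented string at offset ``start``."""

    text: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.text)


class Segmenter(Protocol):
    def __call__(self, text: str) -> list[Segment]: ...


def _to_segments(words: Sequence[str], original: str) -> list[Segment]:
    segments: list[Segment] = []
    pos = 0
    for word in words:
        segments.append(Segment(text=word, start=pos))
        pos += len(word)
    if "".join(words) != original:
        raise SegmenterContractError(
            f"segments {words!r} do not concatenate to the input {original!r}"
        )
    return segments


def segment(text: str, lexicon: Iterable[str]) -> list[Segment]:
    """Cut ``text`` into simple words by forward maximum matching.

    Empty lexicon entries are ignored.  Raises ``ValueError`` on empty text
    (there is nothing to segment and callers that pass one have a bug
    upstream).
    """
    if not text:
        raise ValueError("cannot segment empty text")
    words = {w for w in lexicon if w}
    max_len = max((len(w) for w in words), default=0)

    out: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        atom = _ATOMIC_RE.match(text, i)
        if atom:
            out.append(atom.group())
            i = atom.end()
            continue
        matched = None
        for length in range(min(max_len, n - i), 1, -1):
            cand = text[i : i + length]
            if cand in words and not _ATOMIC_RE.search(cand):
                matched = cand
                break
        if matched is None:
            matched = text[i]  # single code point fallback
        out.append(matched)
        i += len(matched)
    return _to_segments(out, text)


class FmmSegmenter:
    """The built-in forward-maximum-matching segmenter bound to a lexicon."""

    def __init__(self, lexicon: Iterable[str]):
        self.lexicon = frozenset(w for w in lexicon if w)

    def __call__(self, text: str) -> list[Segment]:
        return segment(text, self.lexicon)


def register_segmenter(adapter: Callable[[str], Sequence[str]]) -> Segmenter:
    """Wrap an external word-list segmenter into the :class:`Segmenter` contract.

    The adapter maps text to a word list; the wrapper computes offsets and
    raises :class:`SegmenterContractError` if the words do not reconstruct
    the input (a dropped or altered character would silently corrupt every
    downstream span offset, so this is checked on every call).
    """

    def wrapped(text: str) -> list[Segment]:
        if not text:
            raise ValueError("cannot segment empty text")
        return _to_segments(list(adapter(text)), text)

    return wrapped


def read_word_list(path: str | Path) -> list[str]:
    """Read a one-word-per-line UTF-8 lexicon file."""
    with open(path, encoding="utf-8") as fh:
        return [w for w in (line.strip() for line in fh) if w]
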