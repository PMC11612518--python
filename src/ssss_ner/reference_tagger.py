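"""Pluggable tagger interface and a deterministic gazetteer tagger.

The augment -> train -> evaluate loop needs *some* tagger to close it.
Neural sequence taggers are deliberately out of this package's scope; what
is provided instead is (a) the minimal contract any external tagger must
satisfy to be scored here, and (b) a dictionary (gazetteer) tagger built
from the training corpus: it collects every training entity surface with
its majority type and labels test text by greedy left-to-right longest
match.

A gazetteer is the sharpest possible probe of augmentation: it recognizes a
surface iff that exact surface occurred in (possibly augmented) training
data, so any recall gained on unseen-surface mentions is attributable to
the synthesized variants and nothing else.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

from .corpus_io import EntitySpan, Sentence, TaggedSequence, bio_to_spans, spans_to_bio

__all__ = [
    "Gazetteer",
    "Tagger",
    "TaggerContractError",
    "build_gazetteer",
    "tag",
    "GazetteerTagger",
    "validate_predictions",
]

logger = logging.getLogger(__name__)


class TaggerContractError(Exception):
    """A tagger's output violates the predict() contract."""


@dataclass
class Gazetteer:
    """Entity surface -> entity type, one type per surface.

    Conflicting observations are resolved by majority vote; ties go to the
    lexicographically smallest type name (and are logged, since a tie means
    the dictionary genuinely cannot distinguish the types).
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def build_gazetteer(train: Iterable[Sentence | object]) -> Gazetteer:
    """Collect all training entity surfaces with their majority type."""
    votes: dict[str, Counter] = defaultdict(Counter)
    for item in train:
        for ent in item.entities:
            votes[ent.surface][ent.etype] += 1
    if not votes:
        logger.warning("building gazetteer from an empty corpus")
    entries: dict[str, str] = {}
    for surface, counter in votes.items():
        top = max(counter.values())
        winners = sorted(t for t, c in counter.items() if c == top)
        if len(winners) > 1:
            logger.info(
                "type tie for surface %r (%s); keeping %r",
                surface, dict(counter), winners[0],
            )
        entries[surface] = winners[0]
    return Gazetteer(entries=entries)


def tag(text: str, gazetteer: Gazetteer) -> TaggedSequence:
    """Greedy left-to-right longest-match dictionary tagging.

    At each position the longest gazetteer surface starting there is
    tagged B/I with its type and the scan resumes after it; unmatched
    characters are O.  Longer match beats shorter, leftmost beats later —
    fully deterministic.
    """
    if not gazetteer.entries:
        return TaggedSequence(chars=tuple(text), tags=("O",) * len(text))
    max_len = max(len(s) for s in gazetteer.entries)
    spans: list[EntitySpan] = []
    i = 0
    n = len(text)
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = text[i : i + length]
            if cand in gazetteer.entries:
                hit = EntitySpan(i, i + length, gazetteer.entries[cand], cand)
                break
        if hit is None:
            i += 1
        else:
            spans.append(hit)
            i = hit.end
    return spans_to_bio(Sentence(text=text, entities=tuple(spans)))


class Tagger(Protocol):
    """Contract for any tagger scored by this package: one BIO-valid tag
    sequence per input sentence, each exactly as long as its text."""

    def predict(self, sentences: Sequence[Sentence]) -> list[TaggedSequence]: ...


@dataclass
class GazetteerTagger:
    """The dictionary tagger wrapped in the :class:`Tagger` interface."""

    gazetteer: Gazetteer

    @classmethod
    def fit(cls, train: Iterable[Sentence | object]) -> "GazetteerTagger":
        return cls(gazetteer=build_gazetteer(train))

    def predict(self, sentences: Sequence[Sentence]) -> list[TaggedSequence]:
        return [tag(s.text, self.gazetteer) for s in sentences]

    def predict_sentences(self, sentences: Sequence[Sentence]) -> list[Sentence]:
        """Predictions as span-annotated Sentences, aligned with the input."""
        preds = validate_predictions(sentences, self.predict(sentences))
        return [
            bio_to_spans(seq, parent_id=s.parent_id)
            for s, seq in zip(sentences, preds)
        ]


def validate_predictions(
    sentences: Sequence[Sentence], predictions: Sequence[TaggedSequence]
) -> Sequence[TaggedSequence]:
    """Enforce the tagger contract; returns the predictions unchanged.

    Raises :class:`TaggerContractError` on count or length mismatch.  BIO
    validity is guaranteed by :class:`TaggedSequence` itself, so an adapter
    that produced raw tag lists fails at construction time.
    """
    if len(sentences) != len(predictions):
        raise TaggerContractError(
            f"{len(sentences)} sentences but {len(predictions)} predictions"
        )
    for i, (sent, seq) in enumerate(zip(sentences, predictions)):
        if seq.text != sent.text:
            raise TaggerContractError(
                f"sentence {i}: prediction text does not match input "
                f"({seq.text!r} vs {sent.text!r})"
            )
    return predictions
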