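"""Strict entity-level evaluation and entity-frequency stratification.

A predicted mention counts as correct only if its start offset, end offset
and entity type all equal those of a gold mention — the standard strict
criterion for clinical NER shared tasks.  Matching is one-to-one within a
sentence; unmatched predictions are false positives, unmatched gold
mentions false negatives.  Precision, recall and F1 are micro-averaged over
the corpus, overall and per entity type.

The stratified view partitions gold test mentions by how often their exact
(surface, type) pair occurs among the training mentions:

* unknown — frequency 0,
* low frequency — 0 < frequency < threshold (default 5),
* high frequency — frequency >= threshold.

This isolates the regime data augmentation is supposed to help: mentions a
model never, or rarely, saw during training.  A matched prediction is
credited to its gold mention's stratum; an unmatched (false-positive)
prediction is assigned by its own training frequency, the one convention
point the strict-match definition leaves open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_io import EntitySpan, Sentence

__all__ = [
    "Metrics",
    "EvalReport",
    "FrequencyStrata",
    "STRATA",
    "match_entities",
    "score",
    "stratify",
    "score_by_stratum",
]

STRATA = ("unknown", "low", "high")


@dataclass(frozen=True)
class Metrics:
    """TP/FP/FN counts with derived percentage P/R/F1.

    ``precision`` is ``None`` (undefined) when nothing was predicted;
    recall likewise when there is no gold.  F1 is 0 whenever P + R is 0 or
    either is undefined.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else None

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


@dataclass
class EvalReport:
    """Micro-averaged metrics overall and per entity type."""

    overall: Metrics = field(default_factory=Metrics)
    per_type: dict[str, Metrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall.to_dict(),
            "per_type": {t: m.to_dict() for t, m in sorted(self.per_type.items())},
        }


def match_entities(
    gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]
) -> tuple[int, int, int]:
    """One-to-one strict matching within a sentence -> (TP, FP, FN).

    Two mentions match iff (start, end, type) are identical, so greedy
    multiset intersection is exact — no assignment problem arises.
    """
    gold_keys = Counter((e.start, e.end, e.etype) for e in gold)
    pred_keys = Counter((e.start, e.end, e.etype) for e in pred)
    tp = sum((gold_keys & pred_keys).values())
    fp = sum(pred_keys.values()) - tp
    fn = sum(gold_keys.values()) - tp
    return tp, fp, fn


def _check_aligned(gold: Sequence[Sentence], pred: Sequence[Sentence]) -> None:
    if len(gold) != len(pred):
        raise ValueError(
            f"gold has {len(gold)} sentences but pred has {len(pred)}"
        )
    for i, (g, p) in enumerate(zip(gold, pred)):
        if g.text != p.text:
            raise ValueError(
                f"sentence {i}: gold text {g.text!r} != pred text {p.text!r}"
            )


def score(gold: Sequence[Sentence], pred: Sequence[Sentence]) -> EvalReport:
    """Corpus-level strict entity scoring, overall and per type.

    ``gold`` and ``pred`` must be aligned sentence-by-sentence (same texts
    in the same order); a mismatch raises ``ValueError`` rather than
    silently scoring the wrong pairing.
    """
    _check_aligned(gold, pred)
    report = EvalReport()
    per_type: dict[str, Metrics] = {}
    overall = Metrics()
    for g, p in zip(gold, pred):
        overall = overall + Metrics(*match_entities(g.entities, p.entities))
        types = {e.etype for e in g.entities} | {e.etype for e in p.entities}
        for t in types:
            m = Metrics(*match_entities(
                [e for e in g.entities if e.etype == t],
                [e for e in p.entities if e.etype == t],
            ))
            per_type[t] = per_type.get(t, Metrics()) + m
    report.overall = overall
    report.per_type = per_type
    return report


@dataclass
class FrequencyStrata:
    """Training-frequency table and the unknown/low/high threshold.

    ``key`` selects the counting key: ``"surface_type"`` (exact surface
    string and entity type, the default) or ``"surface"`` (surface alone).
    """

    counts: Counter = field(default_factory=Counter)
    threshold: int = 5
    key: str = "surface_type"

    def _key(self, ent: EntitySpan):
        return (ent.surface, ent.etype) if self.key == "surface_type" else ent.surface

    def frequency(self, ent: EntitySpan) -> int:
        return self.counts[self._key(ent)]

    def stratum_of(self, ent: EntitySpan) -> str:
        f = self.frequency(ent)
        if f == 0:
            return "unknown"
        return "low" if f < self.threshold else "high"


def stratify(
    train: Iterable[Sentence | "object"],
    threshold: int = 5,
    key: str = "surface_type",
) -> FrequencyStrata:
    """Count training-entity occurrences to define test-time strata.

    Accepts any iterable of objects with an ``entities`` attribute
    (Records or Sentences).
    """
    if key not in ("surface_type", "surface"):
        raise ValueError(f"unknown stratification key {key!r}")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts: Counter = Counter()
    for item in train:
        for ent in item.entities:
            counts[(ent.surface, ent.etype) if key == "surface_type" else ent.surface] += 1
    return FrequencyStrata(counts=counts, threshold=threshold, key=key)


def score_by_stratum(
    gold: Sequence[Sentence],
    pred: Sequence[Sentence],
    strata: FrequencyStrata,
) -> dict[str, EvalReport]:
    """Strict scoring restricted to each frequency stratum.

    Every gold mention belongs to exactly one stratum (a partition), so
    per-stratum TP/FP/FN sum to the unstratified counts.  Matched
    predictions inherit the gold mention's stratum; unmatched predictions
    are binned by their own training frequency.
    """
    _check_aligned(gold, pred)
    reports = {s: EvalReport() for s in STRATA}
    for g, p in zip(gold, pred):
        gold_keys = Counter((e.start, e.end, e.etype) for e in g.entities)
        pred_keys = Counter((e.start, e.end, e.etype) for e in p.entities)
        matched = gold_keys & pred_keys
        for ent in g.entities:
            s = strata.stratum_of(ent)
            k = (ent.start, ent.end, ent.etype)
            rep = reports[s]
            if matched[k] > 0:
                matched[k] -= 1
                gold_keys[k] -= 1
                pred_keys[k] -= 1
                _bump(rep, ent.etype, tp=1)
            else:
                gold_keys[k] -= 1
                _bump(rep, ent.etype, fn=1)
        for ent in p.entities:
            k = (ent.start, ent.end, ent.etype)
            if pred_keys[k] > 0:  # unmatched prediction
                pred_keys[k] -= 1
                _bump(reports[strata.stratum_of(ent)], ent.etype, fp=1)
    return reports


def _bump(report: EvalReport, etype: str, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
    delta = Metrics(tp, fp, fn)
    report.overall = report.overall + delta
    report.per_type[etype] = report.per_type.get(etype, Metrics()) + delta
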