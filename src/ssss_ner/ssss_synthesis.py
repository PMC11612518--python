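"""Segmentation Synonym Sentence Synthesis (SSSS) — the augmentation core.

Clinical NER training sets are small and imbalanced: disease and treatment
mentions are scarce, and many test-time mentions never occur in training.
SSSS expands a span-annotated corpus by rewriting the mentions themselves:

1. segment each entity mention into simple words (:mod:`.segmentation`);
2. look up ranked near-synonyms for each simple word
   (:mod:`.synonym_source`);
3. substitute a synonym for the simple word and resynthesize the sentence,
   re-projecting every entity span across the length change.

Each variant keeps its parent's entity count and type multiset — labels are
inherited, never re-annotated — and all non-entity characters are untouched
(unless context substitution is explicitly enabled).  The whole pipeline is
deterministic for a fixed seed: candidate ranking is deterministic, variants
are emitted in a canonical order, and the per-sentence sampling used to cap
variant counts draws from an RNG stream derived from (seed, sentence id), so
capping one sentence never perturbs another.

Span re-projection is the delicate part and lives in :func:`project_spans`:
replacing ``region`` by a string of different length shifts every later
offset by the length delta, and the span containing the region stretches and
has its surface re-sliced.  All span invariants are re-validated on every
variant, so an arithmetic slip can never silently produce a corrupt corpus.
"""

from __future__ import annotations

import hashlib
import itertools
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .corpus_io import (
    EntitySpan,
    Record,
    Sentence,
    ValidationError,
    split_sentences,
)
from .segmentation import Segmenter
from .synonym_source import (
    DEFAULT_MAX_DIST,
    DEFAULT_TOP_K,
    SynonymLexicon,
    find_synonyms,
)

__all__ = [
    "AugmentationConfig",
    "AugmentationReport",
    "project_spans",
    "synthesize_sentence",
    "augment_corpus",
]

CONTEXT_INDEX = -1  # entity index recorded for context (non-entity) substitutions


@dataclass(frozen=True)
class AugmentationConfig:
    """Tunable knobs of the SSSS pipeline.

    min_segments
        An entity is eligible only if its mention cuts into at least this
        many simple words.  Default 1: every entity is eligible, which is
        what the worked single-word substitutions (头昏 -> 头晕) require.
    top_k, max_dist
        Synonym retrieval breadth; see :func:`~.synonym_source.find_synonyms`.
    policy
        ``"single"`` emits one variant per (entity, segment, candidate)
        triple; ``"cross-product"`` additionally emits every combination of
        per-segment choices within an entity (each segment keeps its surface
        or takes one candidate; at least one substitution).
    max_variants_per_sentence
        Cap applied by seeded uniform sampling; ``None`` means uncapped.
    dedupe
        Drop variants whose text duplicates the original sentence or an
        earlier variant.
    substitute_context
        Also substitute simple words of the non-entity context.  Off by
        default: label projection is only provably safe inside mentions.
    """

    min_segments: int = 1
    top_k: int = DEFAULT_TOP_K
    max_dist: int = DEFAULT_MAX_DIST
    policy: str = "single"
    max_variants_per_sentence: int | None = None
    dedupe: bool = True
    seed: int = 0
    substitute_context: bool = False

    def __post_init__(self) -> None:
        if self.min_segments < 1:
            raise ValueError("min_segments must be >= 1")
        if self.max_variants_per_sentence is not None and self.max_variants_per_sentence < 0:
            raise ValueError("max_variants_per_sentence must be >= 0")
        if self.policy not in ("single", "cross-product"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass
class AugmentationReport:
    """Expansion accounting: entity counts per type before and after."""

    pre_counts: dict[str, int] = field(default_factory=dict)
    post_counts: dict[str, int] = field(default_factory=dict)
    variants_per_sentence: dict[str, int] = field(default_factory=dict)

    def expansion_factor(self, etype: str) -> float:
        pre = self.pre_counts.get(etype, 0)
        post = self.post_counts.get(etype, 0)
        return post / pre if pre else float("nan")

    @property
    def n_variants(self) -> int:
        return sum(self.variants_per_sentence.values())

    def to_dict(self) -> dict:
        types = sorted(set(self.pre_counts) | set(self.post_counts))
        return {
            "per_type": {
                t: {
                    "pre": self.pre_counts.get(t, 0),
                    "post": self.post_counts.get(t, 0),
                    "factor": self.expansion_factor(t),
                }
                for t in types
            },
            "total_pre": sum(self.pre_counts.values()),
            "total_post": sum(self.post_counts.values()),
            "variants_per_sentence": dict(self.variants_per_sentence),
        }


# ---------------------------------------------------------------------------
# Span re-projection
# ---------------------------------------------------------------------------


def project_spans(
    sentence: Sentence, region: tuple[int, int], replacement: str
) -> Sentence:
    """Replace ``text[region]`` by ``replacement`` and shift spans across it.

    The region must not cross an entity boundary: it lies either entirely
    inside one span (which stretches by the length delta and has its surface
    re-sliced) or entirely outside all spans.  Spans before the region are
    unchanged; spans after shift by the delta.  The resulting sentence is
    fully re-validated.
    """
    start, end = region
    if not (0 <= start < end <= len(sentence.text)):
        raise ValidationError(f"region {region} out of range")
    if not replacement:
        raise ValidationError("replacement must be non-empty")

    delta = len(replacement) - (end - start)
    new_text = sentence.text[:start] + replacement + sentence.text[end:]

    new_entities: list[EntitySpan] = []
    for ent in sentence.entities:
        if ent.end <= start:
            new_entities.append(ent)
        elif ent.start >= end:
            new_entities.append(ent.shifted(delta))
        elif ent.start <= start and end <= ent.end:
            ns, ne = ent.start, ent.end + delta
            new_entities.append(
                EntitySpan(ns, ne, ent.etype, new_text[ns:ne])
            )
        else:
            raise ValidationError(
                f"region {region} crosses the boundary of span "
                f"({ent.start}, {ent.end}) {ent.surface!r}"
            )
    return replace(sentence, text=new_text, entities=tuple(new_entities))


# ---------------------------------------------------------------------------
# Sentence synthesis
# ---------------------------------------------------------------------------


def _substitution_sites(
    sentence: Sentence,
    segmenter: Segmenter,
    lexicon: SynonymLexicon,
    config: AugmentationConfig,
) -> list[tuple[int, list[tuple[int, int, str, list[str]]]]]:
    """Per eligible entity: (entity index, [(abs start, abs end, segment
    text, candidate words), ...]).  Context runs get entity index -1."""
    sites = []
    for idx, ent in enumerate(sentence.entities):
        segs = segmenter(ent.surface)
        if len(segs) < config.min_segments:
            continue
        seg_entries = []
        for seg in segs:
            cands = find_synonyms(seg.text, lexicon, config.top_k, config.max_dist)
            if cands:
                seg_entries.append(
                    (ent.start + seg.start, ent.start + seg.end, seg.text,
                     [c.word for c in cands])
                )
        if seg_entries:
            sites.append((idx, seg_entries))

    if config.substitute_context:
        covered = [(e.start, e.end) for e in sentence.entities]
        pos = 0
        runs = []
        for s, e in covered + [(len(sentence.text), len(sentence.text))]:
            if pos < s:
                runs.append((pos, sentence.text[pos:s]))
            pos = e
        ctx_entries = []
        for base, run in runs:
            for seg in segmenter(run):
                cands = find_synonyms(seg.text, lexicon, config.top_k,
                                      config.max_dist)
                if cands:
                    ctx_entries.append(
                        (base + seg.start, base + seg.end, seg.text,
                         [c.word for c in cands])
                    )
        if ctx_entries:
            sites.append((CONTEXT_INDEX, ctx_entries))
    return sites


def _apply(
    sentence: Sentence,
    subs: Sequence[tuple[int, int, int, str, str]],
) -> Sentence:
    """Apply (entity idx, abs start, abs end, segment, replacement) subs,
    right to left so earlier offsets stay valid, and mark provenance."""
    out = sentence
    for _, s, e, _, repl in sorted(subs, key=lambda x: -x[1]):
        out = project_spans(out, (s, e), repl)
    return replace(
        out,
        provenance="synthesized",
        substitutions=tuple((i, seg, repl) for i, _, _, seg, repl in subs),
    )


def synthesize_sentence(
    sentence: Sentence,
    segmenter: Segmenter,
    lexicon: SynonymLexicon,
    config: AugmentationConfig = AugmentationConfig(),
    rng: random.Random | None = None,
) -> list[Sentence]:
    """Emit every SSSS variant of one sentence under the given policy.

    Returns an empty list when no entity is eligible or no segment has a
    synonym.  Variants appear in canonical order (entities left to right,
    segments left to right, candidates in retrieval rank order); the
    optional cap subsamples that list with ``rng``, preserving order.
    """
    sites = _substitution_sites(sentence, segmenter, lexicon, config)
    variants: list[Sentence] = []
    for ent_idx, seg_entries in sites:
        for s, e, seg_text, cands in seg_entries:
            for cand in cands:
                variants.append(_apply(sentence, [(ent_idx, s, e, seg_text, cand)]))
        if config.policy == "cross-product" and len(seg_entries) > 1:
            choice_lists = [[None] + list(cands) for *_ , cands in seg_entries]
            for combo in itertools.product(*choice_lists):
                n_subs = sum(c is not None for c in combo)
                if n_subs < 2:  # singles already emitted above
                    continue
                subs = [
                    (ent_idx, s, e, seg_text, cand)
                    for (s, e, seg_text, _), cand in zip(seg_entries, combo)
                    if cand is not None
                ]
                variants.append(_apply(sentence, subs))

    if config.dedupe:
        seen = {(sentence.text, sentence.entities)}
        unique = []
        for v in variants:
            key = (v.text, v.entities)
            if key not in seen:
                seen.add(key)
                unique.append(v)
        variants = unique

    cap = config.max_variants_per_sentence
    if cap is not None and len(variants) > cap:
        if rng is None:
            rng = _sentence_rng(config.seed, sentence.parent_id)
        keep = sorted(rng.sample(range(len(variants)), cap))
        variants = [variants[i] for i in keep]
    return variants


def _sentence_rng(seed: int, parent_id: str) -> random.Random:
    """A dedicated RNG stream per sentence: capping is local, so corpus-level
    output stays byte-identical under reordering-free edits elsewhere."""
    digest = hashlib.sha256(f"{seed}:{parent_id}".encode("utf-8")).digest()
    return random.Random(int.from_bytes(digest[:4], "big"))


# ---------------------------------------------------------------------------
# Corpus-level driver
# ---------------------------------------------------------------------------


def augment_corpus(
    records: Iterable[Record | Sentence],
    segmenter: Segmenter,
    lexicon: SynonymLexicon,
    config: AugmentationConfig = AugmentationConfig(),
    separators: Sequence[str] | None = None,
    split_policy: str = "error",
) -> tuple[list[Sentence], AugmentationReport]:
    """Run SSSS over a corpus: originals plus all synthesized variants.

    Records are first split at the sentence separator (Chinese period by
    default); pre-split :class:`Sentence` inputs are used as-is.  The output
    order — each original followed by its variants — and all contents are a
    deterministic function of (inputs, lexicon, config).
    """
    report = AugmentationReport()
    out: list[Sentence] = []
    for rec in records:
        if isinstance(rec, Sentence):
            sentences = [rec]
        else:
            kwargs = {"policy": split_policy}
            if separators is not None:
                kwargs["separators"] = separators
            sentences = split_sentences(rec, **kwargs)
        for sent in sentences:
            for ent in sent.entities:
                report.pre_counts[ent.etype] = report.pre_counts.get(ent.etype, 0) + 1
            variants = synthesize_sentence(sent, segmenter, lexicon, config)
            report.variants_per_sentence[sent.parent_id] = len(variants)
            out.append(sent)
            out.extend(variants)
    for sent in out:
        for ent in sent.entities:
            report.post_counts[ent.etype] = report.post_counts.get(ent.etype, 0) + 1
    return out, report
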