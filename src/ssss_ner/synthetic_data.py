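"""Hermetic synthetic fixtures: corpora with controlled entity frequencies.

Real clinical NER releases are license-restricted, so every test and demo
in this package runs on generated data instead.  The generator emulates the
*structure* of such corpora, not their prose: short template sentences with
typed entity spans at exactly planned training frequencies, a matching
synonym lexicon with known groups, and a test set whose "unknown" mentions
are precisely the synonym variants the augmenter can synthesize from the
training set.  That last property is what makes the end-to-end benchmark
sharp: a dictionary tagger trained without augmentation cannot recall a
single unknown mention, and with augmentation it recalls exactly those
surfaces SSSS produced.

Frequencies are realized exactly, not in expectation; the default inventory
mirrors the imbalance typical of clinical corpora (disease and treatment
mentions scarce, examination and anatomy mentions common).  Two unknown
surfaces are superstrings of low-frequency training surfaces, so the
unaugmented tagger commits boundary-error false positives that land in the
low-frequency stratum — the mechanism by which augmentation also lifts
low-frequency F1, not only unknown recall.

Everything is a pure function of (spec, seed): rerunning yields
byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import EntitySpan, Record, write_records
from .segmentation import segment
from .synonym_source import SynonymLexicon

__all__ = [
    "SpecError",
    "EntityPlan",
    "VariantPlan",
    "SyntheticSpec",
    "SyntheticDataset",
    "default_spec",
    "generate",
]


class SpecError(Exception):
    """The synthetic spec is internally inconsistent."""


@dataclass(frozen=True)
class EntityPlan:
    """One training-inventory surface with exact train/test occurrence counts."""

    surface: str
    etype: str
    train_freq: int
    test_freq: int = 0


@dataclass(frozen=True)
class VariantPlan:
    """A reserved unknown-stratum surface: appears only in the test set and
    must be derivable from ``source`` by one synonym substitution."""

    surface: str
    etype: str
    test_freq: int
    source: str


@dataclass(frozen=True)
class SyntheticSpec:
    entities: tuple[EntityPlan, ...]
    variants: tuple[VariantPlan, ...]
    synonym_groups: dict[str, tuple[str, ...]]
    one_slot_templates: tuple[tuple[str, str], ...]
    two_slot_templates: tuple[tuple[str, str, str], ...]
    two_slot_prob: float = 0.3
    max_sentences_per_record: int = 3
    n_train: int | None = None  # records; None = as many as the plan needs
    n_test: int | None = None
    threshold: int = 5  # low/high stratum boundary, for the manifest
    seed: int = 7


@dataclass
class SyntheticDataset:
    train: list[Record]
    test: list[Record]
    lexicon: SynonymLexicon
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write train.jsonl, test.jsonl, lexicon.tsv and manifest.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "train": outdir / "train.jsonl",
            "test": outdir / "test.jsonl",
            "lexicon": outdir / "lexicon.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_records(self.train, paths["train"])
        write_records(self.test, paths["test"])
        self.lexicon.to_tsv(paths["lexicon"])
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, ensure_ascii=False, indent=2,
                      sort_keys=True)
            fh.write("\n")
        return paths


def default_spec(seed: int = 7) -> SyntheticSpec:
    """The default benchmark: 5 entity types, scarce disease/treatment,
    curated synonym groups covering every reserved unknown surface."""
    entities = (
        EntityPlan("心电图", "Exam", train_freq=8, test_freq=2),
        EntityPlan("盆腔MRI", "Exam", train_freq=6, test_freq=1),
        EntityPlan("颈动脉彩超", "Exam", train_freq=2, test_freq=1),
        EntityPlan("头昏", "Symptom", train_freq=7, test_freq=2),
        EntityPlan("恶心", "Symptom", train_freq=3, test_freq=1),
        EntityPlan("右手中指", "Body", train_freq=6, test_freq=1),
        EntityPlan("胸腔", "Body", train_freq=5, test_freq=1),
        EntityPlan("左侧胸腔", "Body", train_freq=2, test_freq=1),
        EntityPlan("多发脑梗死", "Disease", train_freq=1, test_freq=1),
        EntityPlan("头孢哌酮", "Treatment", train_freq=2, test_freq=1),
    )
    variants = (
        VariantPlan("双侧颈动脉彩超", "Exam", test_freq=2, source="颈动脉彩超"),
        VariantPlan("盆腔核磁共振检查", "Exam", test_freq=1, source="盆腔MRI"),
        VariantPlan("头晕", "Symptom", test_freq=2, source="头昏"),
        VariantPlan("右中指", "Body", test_freq=1, source="右手中指"),
        VariantPlan("右侧胸腔", "Body", test_freq=1, source="左侧胸腔"),
        VariantPlan("多发脑梗塞", "Disease", test_freq=1, source="多发脑梗死"),
        VariantPlan("头孢哌酮舒巴坦钠", "Treatment", test_freq=1, source="头孢哌酮"),
    )
    synonym_groups = {
        "头昏": ("头晕",),
        "右手中指": ("右中指",),
        "颈动脉彩超": ("双侧颈动脉彩超",),
        "头孢哌酮": ("头孢哌酮舒巴坦钠",),
        "MRI": ("核磁共振检查",),
        "左侧": ("右侧",),
        "脑梗死": ("脑梗塞",),
        # segmentation-only headwords (no synonyms)
        "盆腔": (),
        "多发": (),
        "胸腔": (),
        "心电图": (),
        "恶心": (),
    }
    # Context pieces use characters disjoint from every entity/variant
    # surface so no gazetteer surface can appear outside a planned span.
    one_slot = (
        ("患者诉", "约一周"),
        ("入院后可见", "明显"),
        ("复诊提示", "无殊"),
        ("给予", "治疗后好转"),
        ("考虑", "伴有不适"),
    )
    two_slot = (
        ("患者诉", "伴有", "入院"),
        ("复诊可见", "及", "无殊"),
    )
    return SyntheticSpec(
        entities=entities,
        variants=variants,
        synonym_groups=synonym_groups,
        one_slot_templates=one_slot,
        two_slot_templates=two_slot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Materialize the spec into train/test records, lexicon and manifest.

    Raises :class:`SpecError` if a reserved unknown surface is not reachable
    by one synonym substitution from its source, if realized counts drift
    from the plan, or if a known surface leaks into a template context.
    """
    lexicon = SynonymLexicon(groups=dict(spec.synonym_groups))
    _check_variant_reachability(spec, lexicon)
    _check_context_chars(spec)

    rng = random.Random(spec.seed)
    train_occ = [(p.etype, p.surface) for p in spec.entities
                 for _ in range(p.train_freq)]
    test_occ = [(p.etype, p.surface) for p in spec.entities
                for _ in range(p.test_freq)]
    test_occ += [(v.etype, v.surface) for v in spec.variants
                 for _ in range(v.test_freq)]
    rng.shuffle(train_occ)
    rng.shuffle(test_occ)

    train = _pack_records(train_occ, spec, rng, prefix="train", n_records=spec.n_train)
    test = _pack_records(test_occ, spec, rng, prefix="test", n_records=spec.n_test)

    _recount(train, {(p.etype, p.surface): p.train_freq for p in spec.entities},
             "train")
    want_test = {(p.etype, p.surface): p.test_freq for p in spec.entities
                 if p.test_freq}
    for v in spec.variants:
        want_test[(v.etype, v.surface)] = want_test.get((v.etype, v.surface), 0) + v.test_freq
    _recount(test, want_test, "test")
    _check_no_leaks(train + test, spec)

    manifest = _manifest(spec)
    return SyntheticDataset(train=train, test=test, lexicon=lexicon,
                            manifest=manifest)


def _pack_records(
    occurrences: list[tuple[str, str]],
    spec: SyntheticSpec,
    rng: random.Random,
    prefix: str,
    n_records: int | None,
) -> list[Record]:
    """Render occurrences into template sentences, then pack sentences into
    records of 1..max_sentences_per_record sentences."""
    sentences: list[tuple[str, list[EntitySpan]]] = []
    i = 0
    while i < len(occurrences):
        use_two = (
            len(occurrences) - i >= 2
            and spec.two_slot_templates
            and rng.random() < spec.two_slot_prob
        )
        if use_two:
            pre, mid, post = spec.two_slot_templates[
                rng.randrange(len(spec.two_slot_templates))
            ]
            (t1, s1), (t2, s2) = occurrences[i], occurrences[i + 1]
            text = pre + s1 + mid + s2 + post + "。"
            a = len(pre)
            b = len(pre) + len(s1) + len(mid)
            spans = [EntitySpan(a, a + len(s1), t1, s1),
                     EntitySpan(b, b + len(s2), t2, s2)]
            i += 2
        else:
            pre, post = spec.one_slot_templates[
                rng.randrange(len(spec.one_slot_templates))
            ]
            t1, s1 = occurrences[i]
            text = pre + s1 + post + "。"
            a = len(pre)
            spans = [EntitySpan(a, a + len(s1), t1, s1)]
            i += 1
        sentences.append((text, spans))

    records: list[Record] = []
    j = 0
    rid = 0
    while j < len(sentences):
        k = rng.randint(1, spec.max_sentences_per_record)
        chunk = sentences[j : j + k]
        text = ""
        spans: list[EntitySpan] = []
        for stext, sspans in chunk:
            spans.extend(e.shifted(len(text)) for e in sspans)
            text += stext
        records.append(Record(record_id=f"{prefix}-{rid:04d}", text=text,
                              entities=tuple(spans)))
        rid += 1
        j += k

    if n_records is not None:
        if n_records < len(records):
            raise SpecError(
                f"{prefix}: plan needs {len(records)} records but "
                f"n_records={n_records}"
            )
        while len(records) < n_records:  # pad with entity-free records
            pre, post = spec.one_slot_templates[
                rng.randrange(len(spec.one_slot_templates))
            ]
            records.append(
                Record(record_id=f"{prefix}-{rid:04d}", text=pre + post + "。")
            )
            rid += 1
    return records


def _check_variant_reachability(
    spec: SyntheticSpec, lexicon: SynonymLexicon
) -> None:
    """Every reserved unknown surface must follow from its source by one
    segment-level synonym substitution (checked by brute force)."""
    train_surfaces = {(p.etype, p.surface) for p in spec.entities
                      if p.train_freq > 0}
    words = lexicon.words()
    for v in spec.variants:
        if (v.etype, v.source) not in train_surfaces:
            raise SpecError(
                f"variant {v.surface!r}: source {v.source!r}/{v.etype} is "
                f"not a training surface"
            )
        reachable = set()
        for seg in segment(v.source, words):
            for syn in lexicon.group_of(seg.text):
                reachable.add(
                    v.source[: seg.start] + syn + v.source[seg.end :]
                )
        if v.surface not in reachable:
            raise SpecError(
                f"variant {v.surface!r} is not one substitution away from "
                f"{v.source!r} (reachable: {sorted(reachable)})"
            )


def _check_context_chars(spec: SyntheticSpec) -> None:
    surface_chars = set()
    for p in spec.entities:
        surface_chars.update(p.surface)
    for v in spec.variants:
        surface_chars.update(v.surface)
    for w in spec.synonym_groups:
        surface_chars.update(w)
        for s in spec.synonym_groups[w]:
            surface_chars.update(s)
    ctx = "".join(
        "".join(t) for t in spec.one_slot_templates + spec.two_slot_templates
    )
    clash = set(ctx) & surface_chars
    if clash:
        raise SpecError(
            f"template context shares characters with entity surfaces: "
            f"{sorted(clash)}"
        )


def _recount(records: list[Record], want: dict[tuple[str, str], int],
             which: str) -> None:
    got: dict[tuple[str, str], int] = {}
    for rec in records:
        for ent in rec.entities:
            got[(ent.etype, ent.surface)] = got.get((ent.etype, ent.surface), 0) + 1
    if got != {k: v for k, v in want.items() if v}:
        raise SpecError(f"{which}: realized counts {got} != planned {want}")


def _check_no_leaks(records: list[Record], spec: SyntheticSpec) -> None:
    """No known surface may occur in any text outside a planned span."""
    surfaces = {p.surface for p in spec.entities} | {v.surface for v in spec.variants}
    for rec in records:
        for s in surfaces:
            start = rec.text.find(s)
            while start != -1:
                end = start + len(s)
                if not any(e.start <= start and end <= e.end
                           for e in rec.entities):
                    raise SpecError(
                        f"record {rec.record_id}: surface {s!r} leaks into "
                        f"context at offset {start}"
                    )
                start = rec.text.find(s, start + 1)


def _manifest(spec: SyntheticSpec) -> dict:
    def stratum(freq: int) -> str:
        if freq == 0:
            return "unknown"
        return "low" if freq < spec.threshold else "high"

    rows = [
        {
            "surface": p.surface,
            "type": p.etype,
            "train_freq": p.train_freq,
            "test_freq": p.test_freq,
            "stratum": stratum(p.train_freq),
        }
        for p in spec.entities
    ]
    rows += [
        {
            "surface": v.surface,
            "type": v.etype,
            "train_freq": 0,
            "test_freq": v.test_freq,
            "stratum": "unknown",
            "source": v.source,
        }
        for v in spec.variants
    ]
    return {"threshold": spec.threshold, "seed": spec.seed, "surfaces": rows}
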