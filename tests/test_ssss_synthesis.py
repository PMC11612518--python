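"""Span re-projection, variant synthesis, and corpus augmentation."""

import json
import random

import pytest

from ssss_ner import (
    AugmentationConfig,
    EntitySpan,
    FmmSegmenter,
    Sentence,
    SynonymLexicon,
    ValidationError,
    augment_corpus,
    find_synonyms,
    project_spans,
    segment,
    synthesize_sentence,
    write_records,
)


@pytest.fixture()
def exam_sentence():
    return Sentence(
        text="心电图, 颈动脉彩超等检查",
        entities=(
            EntitySpan(0, 3, "Exam", "心电图"),
            EntitySpan(5, 10, "Exam", "颈动脉彩超"),
        ),
        parent_id="demo-3#0",
    )


class TestProjectSpans:
    def test_longer_replacement_shifts_following_text(self, exam_sentence):
        out = project_spans(exam_sentence, (5, 10), "双侧颈动脉彩超")
        assert out.text == "心电图, 双侧颈动脉彩超等检查"
        first, second = out.entities
        assert first == EntitySpan(0, 3, "Exam", "心电图")  # before: unchanged
        assert (second.start, second.end, second.surface) == (5, 12, "双侧颈动脉彩超")
        assert out.text[second.end:] == "等检查"  # +2 shift of the tail

    def test_equal_length_replacement_keeps_offsets(self):
        sent = Sentence(
            text="主因头部外伤出血伴头昏3.5小时入院",
            entities=(EntitySpan(9, 11, "Symptom", "头昏"),),
        )
        out = project_spans(sent, (9, 11), "头晕")
        (ent,) = out.entities
        assert out.text == "主因头部外伤出血伴头晕3.5小时入院"
        assert (ent.start, ent.end, ent.surface) == (9, 11, "头晕")

    def test_identity_replacement_is_a_no_op(self, exam_sentence):
        out = project_spans(exam_sentence, (0, 3), "心电图")
        assert out.text == exam_sentence.text
        assert out.entities == exam_sentence.entities

    def test_replacement_inside_span_stretches_it(self):
        sent = Sentence(text="盆腔MRI检查", entities=(EntitySpan(0, 5, "Exam", "盆腔MRI"),))
        out = project_spans(sent, (2, 5), "核磁共振检查")
        (ent,) = out.entities
        assert (ent.start, ent.end, ent.surface) == (0, 8, "盆腔核磁共振检查")

    def test_region_crossing_span_boundary_is_an_error(self, exam_sentence):
        with pytest.raises(ValidationError, match="crosses"):
            project_spans(exam_sentence, (2, 6), "甲")

    def test_preceding_span_shrink_shifts_later_span(self, exam_sentence):
        out = project_spans(exam_sentence, (0, 3), "乙")
        first, second = out.entities
        assert (first.start, first.end, first.surface) == (0, 1, "乙")
        assert (second.start, second.end, second.surface) == (3, 8, "颈动脉彩超")


class TestSynthesizeSentence:
    def test_single_word_entity_substitution(self):
        sent = Sentence(
            text="主因头部外伤出血伴头昏3.5小时入院",
            entities=(EntitySpan(9, 11, "Symptom", "头昏"),),
            parent_id="demo-2#0",
        )
        lex = SynonymLexicon(groups={"头昏": ("头晕",)})
        segmenter = FmmSegmenter(lex.words())
        (variant,) = synthesize_sentence(sent, segmenter, lex,
                                         AugmentationConfig(min_segments=1))
        assert variant.text == "主因头部外伤出血伴头晕3.5小时入院"
        assert variant.entities == (EntitySpan(9, 11, "Symptom", "头晕"),)
        assert variant.provenance == "synthesized"
        assert variant.parent_id == "demo-2#0"
        assert variant.substitutions == ((0, "头昏", "头晕"),)

    def test_two_segments_two_candidates_each_gives_four_variants(self):
        lex = SynonymLexicon(groups={"甲乙": ("庚庚", "辛辛"), "丙丁": ("壬壬", "癸癸")})
        sent = Sentence(text="甲乙丙丁也", entities=(EntitySpan(0, 4, "Drug", "甲乙丙丁"),))
        variants = synthesize_sentence(
            sent, FmmSegmenter(lex.words()), lex, AugmentationConfig(max_dist=0)
        )
        assert len(variants) == 4
        assert {v.entities[0].surface for v in variants} == {
            "庚庚丙丁", "辛辛丙丁", "甲乙壬壬", "甲乙癸癸",
        }

    def test_multi_word_entity_inner_substitution(self):
        sent = Sentence(text="盆腔MRI未见异常",
                        entities=(EntitySpan(0, 5, "Exam", "盆腔MRI"),))
        lex = SynonymLexicon(groups={"盆腔": (), "MRI": ("核磁共振检查",)})
        variants = synthesize_sentence(sent, FmmSegmenter(lex.words()), lex,
                                       AugmentationConfig(max_dist=0))
        assert [v.entities[0].surface for v in variants] == ["盆腔核磁共振检查"]
        assert variants[0].text == "盆腔核磁共振检查未见异常"

    def test_min_segments_threshold_excludes_short_entities(self):
        lex = SynonymLexicon(groups={"头昏": ("头晕",)})
        sent = Sentence(text="头昏一周", entities=(EntitySpan(0, 2, "Symptom", "头昏"),))
        variants = synthesize_sentence(
            sent, FmmSegmenter(lex.words()), lex,
            AugmentationConfig(min_segments=2),
        )
        assert variants == []

    def test_context_untouched_by_default(self):
        lex = SynonymLexicon(groups={"头昏": ("头晕",)})
        sent = Sentence(text="头昏头昏时", entities=(EntitySpan(0, 2, "Symptom", "头昏"),))
        (variant,) = synthesize_sentence(sent, FmmSegmenter(lex.words()), lex,
                                         AugmentationConfig())
        # only the entity occurrence is replaced; the context copy stays
        assert variant.text == "头晕头昏时"

    def test_substitute_context_flag_rewrites_outside_spans(self):
        lex = SynonymLexicon(groups={"头昏": ("头晕",)})
        sent = Sentence(text="头昏头昏时", entities=(EntitySpan(0, 2, "Symptom", "头昏"),))
        variants = synthesize_sentence(
            sent, FmmSegmenter(lex.words()), lex,
            AugmentationConfig(substitute_context=True),
        )
        texts = {v.text for v in variants}
        assert "头昏头晕时" in texts  # context substitution, span untouched
        for v in variants:
            if v.text == "头昏头晕时":
                assert v.entities == (EntitySpan(0, 2, "Symptom", "头昏"),)

    def test_cross_product_policy_emits_combinations(self):
        lex = SynonymLexicon(groups={"甲乙": ("庚庚",), "丙丁": ("壬壬",)})
        sent = Sentence(text="甲乙丙丁也", entities=(EntitySpan(0, 4, "Drug", "甲乙丙丁"),))
        variants = synthesize_sentence(
            sent, FmmSegmenter(lex.words()), lex,
            AugmentationConfig(policy="cross-product", max_dist=0),
        )
        surfaces = {v.entities[0].surface for v in variants}
        assert surfaces == {"庚庚丙丁", "甲乙壬壬", "庚庚壬壬"}

    def test_dedupe_drops_textual_duplicates(self):
        # substituting either single-character segment of 甲乙 yields the
        # same text 甲乙乙, so the duplicate must collapse to one variant
        lex = SynonymLexicon(groups={"甲": ("甲乙",), "乙": ("乙乙",)})
        sent = Sentence(text="甲乙后", entities=(EntitySpan(0, 2, "Drug", "甲乙"),))
        seg = FmmSegmenter(())
        deduped = synthesize_sentence(sent, seg, lex,
                                      AugmentationConfig(max_dist=0))
        raw = synthesize_sentence(
            sent, seg, lex, AugmentationConfig(max_dist=0, dedupe=False)
        )
        assert len(raw) == 2 and len(deduped) == 1
        assert {v.text for v in raw} == {"甲乙乙后"}

    def test_variant_cap_is_seeded_and_order_preserving(self):
        lex = SynonymLexicon(groups={"甲": tuple("乙丙丁戊己庚辛")})
        sent = Sentence(text="甲之", entities=(EntitySpan(0, 1, "Drug", "甲"),),
                        parent_id="p#0")
        cfg = AugmentationConfig(max_variants_per_sentence=3, seed=13, max_dist=0)
        seg = FmmSegmenter(lex.words())
        first = synthesize_sentence(sent, seg, lex, cfg)
        second = synthesize_sentence(sent, seg, lex, cfg)
        assert len(first) == 3
        assert [v.text for v in first] == [v.text for v in second]
        full = synthesize_sentence(
            sent, seg, lex, AugmentationConfig(max_dist=0)
        )
        order = [v.text for v in full]
        assert sorted(order.index(v.text) for v in first) == [
            order.index(v.text) for v in first
        ]

    def test_no_eligible_entity_returns_empty(self):
        sent = Sentence(text="无殊")
        assert synthesize_sentence(sent, FmmSegmenter(()), SynonymLexicon(),
                                   AugmentationConfig()) == []


class TestInvariants:
    def test_label_and_context_conservation_on_random_fixtures(self):
        rng = random.Random(21)
        words = ["甲乙", "丙丁丁", "戊己", "庚辛"]
        lex = SynonymLexicon(groups={
            "甲乙": ("子子", "丑丑丑"),
            "丙丁丁": ("寅寅",),
            "戊己": ("卯卯卯卯",),
        })
        seg = FmmSegmenter(words)
        cfg = AugmentationConfig()
        for i in range(150):
            n_ent = rng.randint(1, 2)
            parts, ents, pos = [], [], 0
            for _ in range(n_ent):
                ctx = "之乎者"[: rng.randint(1, 3)]
                parts.append(ctx)
                pos += len(ctx)
                surface = "".join(rng.choice(words) for _ in range(rng.randint(1, 2)))
                parts.append(surface)
                ents.append(EntitySpan(pos, pos + len(surface),
                                       rng.choice(("Drug", "Body")), surface))
                pos += len(surface)
            parts.append("也")
            sent = Sentence(text="".join(parts), entities=tuple(ents),
                            parent_id=f"f#{i}")
            for v in synthesize_sentence(sent, seg, lex, cfg):
                # label conservation: same count and type multiset
                assert len(v.entities) == len(sent.entities)
                assert sorted(e.etype for e in v.entities) == sorted(
                    e.etype for e in sent.entities
                )
                # context preservation: non-entity characters identical
                def context(s):
                    out, p = [], 0
                    for e in s.entities:
                        out.append(s.text[p:e.start])
                        p = e.end
                    out.append(s.text[p:])
                    return out
                assert context(v) == context(sent)

    def test_closed_form_variant_count_on_random_fixtures(self):
        # single-substitution, no cap: exactly sum over entities and
        # segments of the candidate count, checked against independent
        # re-enumeration via segment() + find_synonyms()
        rng = random.Random(22)
        words = ["甲乙", "丙丁", "戊己戊"]
        lex = SynonymLexicon(groups={
            "甲乙": ("子子", "丑丑"),
            "丙丁": ("寅寅", "卯卯", "辰辰"),
        })
        seg = FmmSegmenter(words)
        cfg = AugmentationConfig(dedupe=False)
        for i in range(200):
            surfaces = [
                "".join(rng.choice(words) for _ in range(rng.randint(1, 3)))
                for _ in range(rng.randint(1, 2))
            ]
            text, ents, pos = "", [], 0
            for s in surfaces:
                text += "之"
                pos += 1
                ents.append(EntitySpan(pos, pos + len(s), "Drug", s))
                text += s
                pos += len(s)
            sent = Sentence(text=text, entities=tuple(ents), parent_id=f"c#{i}")
            expected = sum(
                len(find_synonyms(sg.text, lex, cfg.top_k, cfg.max_dist))
                for e in sent.entities
                for sg in segment(e.surface, words)
            )
            got = synthesize_sentence(sent, seg, lex, cfg)
            assert len(got) == expected


class TestAugmentCorpus:
    def test_no_synonyms_means_no_variants(self, demo_records):
        lex = SynonymLexicon(groups={})
        sentences, report = augment_corpus(
            demo_records, FmmSegmenter(()), lex, AugmentationConfig()
        )
        assert all(s.provenance == "original" for s in sentences)
        for etype in report.pre_counts:
            assert report.expansion_factor(etype) == 1.0

    def test_report_counts_match_output(self, demo_records, demo_lexicon):
        seg = FmmSegmenter(demo_lexicon.words())
        sentences, report = augment_corpus(
            demo_records, seg, demo_lexicon, AugmentationConfig(seed=42)
        )
        post = {}
        for s in sentences:
            for e in s.entities:
                post[e.etype] = post.get(e.etype, 0) + 1
        assert post == report.post_counts
        n_variants = sum(1 for s in sentences if s.provenance == "synthesized")
        assert report.n_variants == n_variants

    def test_rerun_is_byte_identical(self, tmp_path, demo_records, demo_lexicon):
        seg = FmmSegmenter(demo_lexicon.words())
        cfg = AugmentationConfig(seed=42, max_variants_per_sentence=5)
        paths = []
        for name in ("a.jsonl", "b.jsonl"):
            sentences, _ = augment_corpus(demo_records, seg, demo_lexicon, cfg)
            path = tmp_path / name
            write_records(sentences, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_report_json_shape(self, demo_records, demo_lexicon):
        seg = FmmSegmenter(demo_lexicon.words())
        _, report = augment_corpus(demo_records, seg, demo_lexicon,
                                   AugmentationConfig(seed=42))
        blob = json.loads(json.dumps(report.to_dict()))
        assert set(blob) == {"per_type", "total_pre", "total_post",
                             "variants_per_sentence"}
        for row in blob["per_type"].values():
            assert row["post"] >= row["pre"]
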