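# ssss-ner

Synonym-substitution data augmentation and strict entity-level evaluation
for clinical named-entity-recognition (NER) corpora.

Clinical NER training sets are small: annotation requires medical
expertise, records are privacy-restricted, and mention types are heavily
imbalanced (disease and treatment mentions are typically far scarcer than
examination or anatomy mentions). As a result, sequence taggers fail
disproportionately on mentions they saw rarely — or never — during
training. This package implements **Segmentation Synonym Sentence
Synthesis (SSSS)**, an augmentation algorithm that expands a
span-annotated corpus by rewriting the entity mentions themselves:

1. **Segment** each entity mention *X* into simple words *X₁ X₂ … Xₘ*
   (forward maximum matching against a word lexicon; e.g. 盆腔MRI → 盆腔 +
   MRI);
2. **Search** ranked near-synonyms for each simple word, combining curated
   synonym groups, Levenshtein edit-distance search over the lexicon, and
   optional word-embedding cosine ranking (e.g. MRI → 核磁共振检查);
3. **Synthesize** a new sentence per substitution, re-projecting every
   entity span across the length change (盆腔MRI → 盆腔核磁共振检查 shifts
   all following offsets by +3).

Variants inherit their parent's labels: entity count, type multiset and
all non-entity context are preserved, and every span is re-validated, so
augmentation can never silently corrupt annotations.

Around the core algorithm the package provides everything needed to close
the loop hermetically:

- `corpus_io` — CCKS-style JSONL span records ↔ per-character BIO/CoNLL
  tags, lossless and validated; sentence splitting on the Chinese period;
- `segmentation` — deterministic forward-maximum-matching segmenter, with
  an adapter contract for external segmenters (e.g. jieba);
- `synonym_source` — file-backed synonym lexicon, Levenshtein search,
  cosine ranking;
- `ssss_synthesis` — the augmentation engine and expansion report;
- `ner_eval` — strict entity-level micro P/R/F1 (a prediction is correct
  only if start, end and type all match), per type, and stratified by
  training frequency: **unknown** (0 training occurrences), **low** (< 5),
  **high** (≥ 5);
- `reference_tagger` — a gazetteer (dictionary longest-match) tagger: the
  sharpest probe of augmentation, since it recalls a mention iff its exact
  surface occurred in training data;
- `synthetic_data` — a generator of corpora with exactly controlled entity
  frequencies and a matching synonym lexicon, used by all tests and demos.

## Worked example

```python
import ssss_ner as s

records = s.load_demo_records()          # four bundled clinical sentences
lexicon = s.load_demo_lexicon()          # mini synonym lexicon (5 groups)
segmenter = s.FmmSegmenter(lexicon.words())
config = s.AugmentationConfig(max_dist=0, seed=42)

sentences, report = s.augment_corpus(records, segmenter, lexicon, config)
for sent in sentences:
    mark = "+" if sent.provenance == "synthesized" else " "
    print(mark, sent.text, [(e.surface, e.etype) for e in sent.entities])
for etype, row in report.to_dict()["per_type"].items():
    print(f"{etype}: {row['pre']} -> {row['post']} entities (x{row['factor']:.1f})")
```

prints

```
  右手中指疼痛不适 [('右手中指', 'Body')]
+ 右中指疼痛不适 [('右中指', 'Body')]
  主因头部外伤出血伴头昏3.5小时入院 [('头昏', 'Symptom')]
+ 主因头部外伤出血伴头晕3.5小时入院 [('头晕', 'Symptom')]
  心电图, 颈动脉彩超等检查 [('心电图', 'Exam'), ('颈动脉彩超', 'Exam')]
+ 心电图, 双侧颈动脉彩超等检查 [('心电图', 'Exam'), ('双侧颈动脉彩超', 'Exam')]
  给予静点头孢哌酮, 炎琥宁联合抗感染 [('头孢哌酮', 'Treatment'), ('炎琥宁', 'Treatment')]
+ 给予静点头孢哌酮舒巴坦钠, 炎琥宁联合抗感染 [('头孢哌酮舒巴坦钠', 'Treatment'), ('炎琥宁', 'Treatment')]
Body: 1 -> 2 entities (x2.0)
Exam: 2 -> 4 entities (x2.0)
Symptom: 1 -> 2 entities (x2.0)
Treatment: 2 -> 4 entities (x2.0)
```

Each `+` line is a synthesized variant: the substituted mention carries
the parent's entity type, the span offsets are re-projected (note the tail
of the carotid sentence shifting by +2), and everything outside the
mention is untouched. `max_dist=0` restricts search to curated synonym
groups; raising it (default 2) additionally pulls in lexicon headwords
within that edit distance of each simple word.

The same pipeline from the shell:

```bash
ssss simulate --outdir fixtures/ --seed 7
ssss augment  --input fixtures/train.jsonl --lexicon fixtures/lexicon.tsv \
              --out aug.jsonl --report report.json --seed 7
ssss tag      --train aug.jsonl --input fixtures/test.jsonl --out pred.jsonl
ssss evaluate --gold fixtures/test.jsonl --pred pred.jsonl \
              --train fixtures/train.jsonl --stratify --out eval.json
```

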