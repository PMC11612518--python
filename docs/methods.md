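# Methods

## The augmentation model

SSSS treats an annotated corpus as a set of sentences, each a character
string with typed, non-overlapping, half-open entity spans. For every
entity mention it (1) cuts the mention into simple words, (2) retrieves
near-synonym candidates per simple word, and (3) emits one new sentence
per substitution, splicing the candidate into the text and shifting all
downstream offsets by the length delta. The model's core assumption is
that a mention with one simple word replaced by a near-synonym is still a
valid mention of the same type in the same context — labels are inherited,
never re-annotated. That assumption is what restricts substitution to
entity-internal vocabulary by default: inside a mention, the span boundary
moves with the splice and the label provably still covers exactly the
rewritten mention. Outside a mention no such guarantee exists, so context
substitution is available only behind an explicit flag
(`substitute_context`), off by default.

No grammaticality or semantic-equivalence checking is attempted: a
synthesized sentence is structurally valid by construction but may be
clinically awkward. This is inherent to substitution-based augmentation
and is the reason the evaluation side of the package exists — the value of
the variants is measured downstream, not assumed.

## Segmentation

The built-in segmenter is forward maximum matching (FMM): greedy
left-to-right, longest lexicon word first, single code point as fallback.
Runs of ASCII letters, or digits with an optional decimal point, are
atomic ("MRI", "3.5"), so alphanumeric tokens embedded in Chinese text are
never split; a consequence is that lexicon words mixing Han and ASCII
characters are not matched as units — their ASCII part is its own token.
FMM was chosen over a statistical segmenter because it is a pure function
of (text, lexicon): the whole augmentation pipeline stays deterministic
and dependency-free. Statistical segmenters plug in through
`register_segmenter`, which enforces the one contract everything
downstream relies on: segments must concatenate exactly to the input
(checked per call — a dropped character would corrupt every later span
offset). Users of external segmenters should record the segmenter version
alongside the corpus, since segmentation changes results.

Greedy longest-match does not resolve genuine segmentation ambiguity; it
just fixes one deterministic answer. That is a known limitation, not a
claim about linguistic correctness.

## Synonym retrieval

The synonym backend is a file-based lexicon (headword → synonym group,
optional embedding vectors) rather than a live nearest-neighbour database,
so retrieval is a deterministic function of a versionable file. Candidates
for a query come from two routes:

- **group route** — the symmetric closure of the query's synonym group,
  *regardless of edit distance*: curated pairs like a drug and its
  compound trade name (头孢哌酮 / 头孢哌酮舒巴坦钠, distance 4) or an
  abbreviation and its expansion (MRI / 核磁共振检查, distance 6) are
  exactly the pairs worth substituting;
- **fuzzy route** — any other headword within `max_dist` Levenshtein edits
  of the query, plus that headword's group. This discovers near-spellings
  (e.g. 梗死 / 梗塞 style variants) but at small `max_dist` on short
  queries it is deliberately noisy: a 2-character query is within 2 edits
  of every 2-character headword. Set `max_dist=0` to disable it.

Ranking is fully specified because ties are common: edit distance
ascending, then cosine similarity descending when both vectors are
present, then lexicographic (Unicode code point order), truncated to
`top_k`. Defaults `top_k=5`, `max_dist=2`; both are surfaced in the CLI
and should be logged with any produced corpus. The query itself is never
returned. Levenshtein distance is the classic two-row unit-cost dynamic
programme over code points; it is verified in the test suite against a
textbook recursive implementation (exhaustively on small-instance domains:
all pairs over a 4-symbol alphabet up to length 4, all pairs over a
2-symbol alphabet up to length 6, and seeded random pairs at lengths 5–6)
and against an independent C implementation (edlib).

## Synthesis policies and determinism

Under the default **single-substitution** policy the variant set is exactly
one sentence per (entity, segment, candidate) triple — linear in the
candidate counts and analyzable in closed form: a sentence whose entities
have kᵢⱼ candidates for segment j of entity i yields Σᵢ Σⱼ kᵢⱼ variants
(before deduplication). The **cross-product** policy additionally emits
every combination of per-segment choices *within* one entity (each segment
keeps its surface or takes one candidate, at least one substitution);
combinations across different entities are not emitted, keeping the
variant count bounded by the product over one entity's segments rather
than the whole sentence's.

Deduplication (on by default) removes variants whose text and spans
duplicate the original or an earlier variant — distinct substitutions can
collide, e.g. replacing 甲→甲乙 at position 0 and 乙→乙乙 at position 1 of
the mention 甲乙 both produce 甲乙乙. An optional per-sentence cap
subsamples the canonical variant list with an RNG stream derived from
(seed, sentence id) via SHA-256, so capping one sentence never perturbs
another and the whole corpus is byte-identical across reruns for a fixed
seed.

The eligibility threshold `min_segments` defaults to 1 (every entity
eligible): single-word mentions such as 头昏 → 头晕 are among the most
useful substitutions, and excluding short mentions is left as an explicit
configuration choice rather than a default.

## Evaluation

Scoring is strict entity-level micro-averaged P/R/F1: a prediction counts
iff (start, end, type) all equal an unmatched gold span; matching is
one-to-one (multiset intersection of exact keys, which is provably
optimal — no assignment problem arises). Precision is reported as
undefined (JSON `null`) when nothing was predicted rather than silently 0;
F1 is 0 whenever either component is undefined or both are 0.

Stratification keys each gold test mention by the training frequency of
its exact (surface, type) pair: unknown = 0, low < threshold, high ≥
threshold, threshold default 5. The key is switchable to surface-only. Two
convention points the strict-match definition leaves open are fixed as
follows and flagged here: (a) matched predictions inherit the gold
mention's stratum; (b) unmatched (false-positive) predictions are binned
by their *own* training frequency — a boundary-error prediction that
reproduces a known training surface is a failure of that surface's
stratum, which is precisely the phenomenon the synthetic benchmark
exploits. Per-stratum counts sum exactly to the unstratified counts (the
strata partition the gold mentions, and every FP lands in exactly one
stratum).

## The gazetteer reference tagger

The in-repo tagger is a dictionary tagger: training-entity surfaces with
majority-vote types (ties to the lexicographically smallest type, logged),
applied by greedy left-to-right longest match. It is deliberately not a
learned model: a gazetteer recalls a mention iff that exact surface was in
its (possibly augmented) training data, so any gain on unseen-surface
mentions is attributable to augmentation alone, with no training variance.
Neural taggers attach through the `Tagger` protocol (`predict` returning
one BIO-valid tag sequence per input sentence, lengths enforced); their
scores are comparable through the same evaluation module.

## The synthetic benchmark

The generator materializes a frequency plan exactly (not in expectation):
each planned (surface, type) pair occurs precisely its planned number of
times in train and test, packed into template sentences (one or two entity
slots) and records of 1–3 period-terminated sentences. Template context
characters are disjoint from all entity characters — validated at
generation time, along with a no-leak scan proving no known surface occurs
in any text outside a planned span — so dictionary matches can only happen
where the plan says they can.

The default plan mimics the imbalance of real clinical corpora
(disease/treatment scarce: frequencies 1–2; exam/anatomy common: 5–8) and
reserves seven unknown-stratum surfaces that appear only in the test set,
each exactly one synonym substitution away from a training surface (also
validated at generation time by brute-force enumeration). Two of them —
双侧颈动脉彩超 and 头孢哌酮舒巴坦钠 — are superstrings of *low-frequency*
training surfaces, so the unaugmented gazetteer tags their inner substring
with wrong boundaries, committing false positives that land in the low
stratum. After augmentation the full surfaces are in the dictionary,
longest match wins, those FPs vanish, and low-frequency F1 strictly
increases (76.92 → 100 under the default plan) while unknown recall goes
from 0 to 1. Stratification always uses the *unaugmented* training corpus:
augmentation changes what a model trains on, not which test mentions count
as unknown.

What passing this benchmark shows: label projection, span arithmetic,
retrieval, reporting and stratified scoring are correct end-to-end, and
the mechanism by which substitution-based augmentation helps rare mentions
operates as described. What it does not show: anything about grammatical
quality of variants, about statistical learners (the gazetteer has no
generalization beyond exact match), or about performance on real clinical
text, whose surface diversity, nested mentions and annotation noise the
generator does not emulate.

## Numerical and scale choices

- Offsets are 0-based half-open everywhere internally; inclusive-end
  corpora are converted at the reader boundary (`span_convention`).
- Tagging is per Unicode code point — the standard granularity for Chinese
  clinical text; no BIOES/BILOU, no nested or discontinuous mentions.
- Sentence splitting keeps the period attached to the preceding sentence,
  so character counts are conserved exactly; a mention straddling a period
  is a hard error by default (`keep-record` falls back to not splitting).
- BIO repair (orphan I-tag promoted to B) exists but is opt-in; strict
  validation is the contract everywhere else.
- Test-suite problem sizes: 10,000 random sentences for the span↔BIO
  round trip, 500 random corpora for scorer/oracle agreement, 200 random
  fixtures for the closed-form variant count, and the edit-distance
  domains listed above. The full suite runs in a few seconds on one CPU;
  the sizes were chosen to exhaust the small-instance spaces that matter
  (boundary offsets, tie-breaks, stratum edges) rather than to maximize
  volume.
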