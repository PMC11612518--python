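"""ssss_ner — Segmentation Synonym Sentence Synthesis for clinical NER.

Data augmentation for span-annotated clinical NER corpora: segment each
entity mention into simple words, substitute near-synonyms, resynthesize
the sentence with all spans re-projected.  Ships with strict entity-level
P/R/F1 scoring, unknown/low/high-frequency stratification, a gazetteer
reference tagger, and a synthetic-corpus generator so the whole
augment -> train -> evaluate loop runs hermetically.
"""

from importlib import resources

from .corpus_io import (
    CorpusError,
    EntitySpan,
    JsonlDialect,
    ParseError,
    Record,
    Sentence,
    TaggedSequence,
    ValidationError,
    bio_to_spans,
    read_bio,
    read_records,
    read_sentences,
    spans_to_bio,
    split_sentences,
    write_bio,
    write_records,
)
from .segmentation import (
    FmmSegmenter,
    Segment,
    SegmenterContractError,
    read_word_list,
    register_segmenter,
    segment,
)
from .synonym_source import (
    SynonymCandidate,
    SynonymLexicon,
    cosine_similarity,
    find_synonyms,
    levenshtein,
)
from .ssss_synthesis import (
    AugmentationConfig,
    AugmentationReport,
    augment_corpus,
    project_spans,
    synthesize_sentence,
)
from .ner_eval import (
    EvalReport,
    FrequencyStrata,
    Metrics,
    match_entities,
    score,
    score_by_stratum,
    stratify,
)
from .reference_tagger import (
    Gazetteer,
    GazetteerTagger,
    TaggerContractError,
    build_gazetteer,
    tag,
    validate_predictions,
)
from .synthetic_data import (
    EntityPlan,
    SpecError,
    SyntheticDataset,
    SyntheticSpec,
    VariantPlan,
    default_spec,
    generate,
)

__version__ = "0.1.0"


def load_demo_records() -> list[Record]:
    """Four short bundled clinical sentences with typed entity spans."""
    with resources.as_file(
        resources.files("ssss_ner") / "data" / "demo.jsonl"
    ) as path:
        return read_records(path)


def load_demo_lexicon() -> SynonymLexicon:
    """The mini synonym lexicon matching the bundled demo sentences."""
    with resources.as_file(
        resources.files("ssss_ner") / "data" / "demo_lexicon.tsv"
    ) as path:
        return SynonymLexicon.from_tsv(path)
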