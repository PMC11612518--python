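"""Ranked near-synonym candidates for a segmented word.

The augmentation step needs, for each simple word of an entity mention, a
small ranked list of near-synonyms.  Production systems back this with a
word2vec nearest-neighbour database; here the backend is abstracted as a
file-based :class:`SynonymLexicon` (headword -> synonym group, optionally
with embedding vectors), so results are a deterministic function of the
lexicon file rather than of a third-party database version.

Candidate retrieval combines two routes:

* the query's own synonym group, taken symmetrically — if the query appears
  as a headword or inside a group, the headword and all co-members are
  candidates, whatever their edit distance (curated synonym pairs such as a
  drug name and its full trade name can be many edits apart);
* a fuzzy fallback: any *other* headword within ``max_dist`` Levenshtein
  edits of the query contributes itself and its group.

Candidates are ranked by (edit distance asc, embedding cosine similarity
desc, lexicographic) and truncated to ``top_k``.  The query itself is never
a candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "levenshtein",
    "cosine_similarity",
    "SynonymLexicon",
    "SynonymCandidate",
    "find_synonyms",
    "DEFAULT_TOP_K",
    "DEFAULT_MAX_DIST",
]

DEFAULT_TOP_K = 5
DEFAULT_MAX_DIST = 2


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute).

    Classic two-row dynamic programme over code points; O(len(a)*len(b))
    time, O(min) memory.
    """
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(
                prev[j] + 1,          # delete from a
                cur[j - 1] + 1,       # insert into a
                prev[j - 1] + (ca != cb),  # substitute
            ))
        prev = cur
    return prev[-1]


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """dot(u, v) / (|u| |v|); raises on zero-norm or mismatched dimension."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class SynonymCandidate:
    """One retrieved synonym: the word, its edit distance to the query, and
    the embedding cosine similarity if both vectors are known (else None)."""

    word: str
    edit_distance: int
    similarity: float | None = None


@dataclass
class SynonymLexicon:
    """Headword -> synonym group, with optional word vectors.

    Invariants: a headword never lists itself as its own synonym; all
    vectors share one dimension.
    """

    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = {h: tuple(s) for h, s in self.groups.items()}
        for head, syns in self.groups.items():
            if head in syns:
                raise ValueError(f"{head!r} listed as its own synonym")
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"vectors have mixed dimensions: {sorted(dims)}")

    # -- file formats -----------------------------------------------------

    @classmethod
    def from_tsv(
        cls, path: str | Path, vectors_path: str | Path | None = None
    ) -> "SynonymLexicon":
        """Read ``headword<TAB>syn1,syn2,...`` lines (empty group allowed),
        and optionally ``word<TAB>v1 v2 ... vd`` vector lines."""
        groups: dict[str, tuple[str, ...]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                head, _, rest = line.partition("\t")
                if not head:
                    raise ValueError(f"{path}:{lineno}: empty headword")
                syns = tuple(s for s in rest.split(",") if s)
                groups[head] = syns
        vectors: dict[str, np.ndarray] = {}
        if vectors_path is not None:
            with open(vectors_path, encoding="utf-8") as fh:
                for raw in fh:
                    line = raw.strip()
                    if not line:
                        continue
                    word, _, nums = line.partition("\t")
                    vectors[word] = np.array(
                        [float(x) for x in nums.split()], dtype=float
                    )
        return cls(groups=groups, vectors=vectors)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for head in sorted(self.groups):
                fh.write(f"{head}\t{','.join(self.groups[head])}\n")

    # -- queries ----------------------------------------------------------

    def words(self) -> set[str]:
        out = set(self.groups)
        for syns in self.groups.values():
            out.update(syns)
        return out

    def group_of(self, word: str) -> set[str]:
        """Symmetric closure: all words sharing a group with ``word``,
        excluding ``word`` itself."""
        related: set[str] = set()
        if word in self.groups:
            related.update(self.groups[word])
        for head, syns in self.groups.items():
            if word in syns:
                related.add(head)
                related.update(syns)
        related.discard(word)
        return related


def find_synonyms(
    query: str,
    lexicon: SynonymLexicon,
    top_k: int = DEFAULT_TOP_K,
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[SynonymCandidate]:
    """Retrieve up to ``top_k`` ranked near-synonyms for ``query``.

    An unknown query with no headword within ``max_dist`` edits yields an
    empty list, not an error: most words of a sentence simply have no
    curated synonyms.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")

    pool = lexicon.group_of(query)
    for head in lexicon.groups:
        if head != query and levenshtein(query, head) <= max_dist:
            pool.add(head)
            pool.update(lexicon.groups[head])
    pool.discard(query)

    qvec = lexicon.vectors.get(query)
    candidates = []
    for word in pool:
        sim = None
        wvec = lexicon.vectors.get(word)
        if qvec is not None and wvec is not None:
            sim = cosine_similarity(qvec, wvec)
        candidates.append(
            SynonymCandidate(word=word, edit_distance=levenshtein(query, word),
                             similarity=sim)
        )
    candidates.sort(
        key=lambda c: (
            c.edit_distance,
            -c.similarity if c.similarity is not None else math.inf,
            c.word,
        )
    )
    return candidates[:top_k]
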