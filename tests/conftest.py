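"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by the most naive method
available (recursion, exhaustive enumeration, quadratic scans) so they stay
independent of the library code paths they check.
"""

from __future__ import annotations

import random
from functools import lru_cache

import pytest

from ssss_ner import (
    EntitySpan,
    Sentence,
    load_demo_lexicon,
    load_demo_records,
)
from ssss_ner.synthetic_data import default_spec, generate


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def demo_records():
    return load_demo_records()


@pytest.fixture(scope="session")
def demo_lexicon():
    return load_demo_lexicon()


@pytest.fixture(scope="session")
def synthetic_dataset():
    return generate(default_spec(seed=7))


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def naive_levenshtein(a: str, b: str) -> int:
    """Textbook recursive edit distance (memoized for tractability only)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        return min(
            rec(i + 1, j) + 1,
            rec(i, j + 1) + 1,
            rec(i + 1, j + 1) + (a[i] != b[j]),
        )

    return rec(0, 0)


def oracle_match(gold, pred):
    """Quadratic greedy one-to-one matching on exact (start, end, type)."""
    used = [False] * len(pred)
    tp = 0
    for g in gold:
        for i, p in enumerate(pred):
            if not used[i] and (p.start, p.end, p.etype) == (g.start, g.end, g.etype):
                used[i] = True
                tp += 1
                break
    return tp, len(pred) - tp, len(gold) - tp


def all_tilings(text: str, words: frozenset) -> list[tuple[str, ...]]:
    """Every way to tile text by lexicon words or single characters."""
    if not text:
        return [()]
    out = []
    options = {text[0]} | {w for w in words if text.startswith(w)}
    for w in options:
        for rest in all_tilings(text[len(w):], words):
            out.append((w,) + rest)
    return out


def greedy_longest_tiling(text: str, words) -> tuple[str, ...]:
    """Forward-maximum-matching reference: among all tilings, pick the one
    whose successive segment lengths are lexicographically largest — i.e.
    the longest word at each position."""
    tilings = all_tilings(text, frozenset(words))
    return max(tilings, key=lambda t: tuple(len(w) for w in t))


# ---------------------------------------------------------------------------
# Random corpus generation for scorer/round-trip stress tests
# ---------------------------------------------------------------------------

ALPHABET = "甲乙丙丁戊己庚辛"
TYPES = ("Body", "Disease", "Drug", "Exam", "Symptom")


def random_sentence(rng: random.Random, max_len: int = 14,
                    parent_id: str = "") -> Sentence:
    n = rng.randint(1, max_len)
    text = "".join(rng.choice(ALPHABET) for _ in range(n))
    spans = []
    i = 0
    while i < n:
        if rng.random() < 0.45:
            end = min(n, i + rng.randint(1, 4))
            spans.append(
                EntitySpan(i, end, rng.choice(TYPES), text[i:end])
            )
            i = end + rng.randint(0, 2)
        else:
            i += 1
    return Sentence(text=text, entities=tuple(spans), parent_id=parent_id)


def random_prediction(rng: random.Random, gold: Sentence) -> Sentence:
    """A perturbed copy of a gold sentence: some spans kept, some mutated
    (boundary or type errors), some hallucinated."""
    spans = []
    occupied = []

    def fits(s, e):
        return all(e <= a or s >= b for a, b in occupied)

    for ent in gold.entities:
        r = rng.random()
        if r < 0.55:
            cand = ent
        elif r < 0.75:
            cand = EntitySpan(ent.start, ent.end, rng.choice(TYPES),
                              ent.surface)
        elif r < 0.9 and ent.end < len(gold.text):
            cand = EntitySpan(ent.start, ent.end + 1, ent.etype,
                              gold.text[ent.start:ent.end + 1])
        else:
            continue
        if fits(cand.start, cand.end):
            spans.append(cand)
            occupied.append((cand.start, cand.end))
    if rng.random() < 0.3 and gold.text:
        s = rng.randrange(len(gold.text))
        e = min(len(gold.text), s + rng.randint(1, 3))
        if fits(s, e):
            spans.append(EntitySpan(s, e, rng.choice(TYPES), gold.text[s:e]))
    spans.sort(key=lambda x: x.start)
    return Sentence(text=gold.text, entities=tuple(spans),
                    parent_id=gold.parent_id)
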