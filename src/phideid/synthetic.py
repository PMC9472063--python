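"""Seeded synthetic annotated corpora emulating a 4-type PHI corpus.

Real clinical records with PHI annotations cannot be shipped, so every
trainable component in this package is exercised on generated corpora.  The
generator emulates the structural properties that matter for the task:

* four entity categories (PER, LOC, ORG, DAT) with a fixed relative
  frequency — defaults follow a clinical training corpus whose original
  annotation counts were 1448 PER, 302 LOC, 846 ORG and 3013 DAT
  (proportions .258 / .054 / .151 / .537);
* variable entity density including entity-sparse sentences (mostly-O
  text is common in record narrative and stresses generation-based
  augmentation);
* per-category mention shape: each category draws its mention tokens from
  its own sub-alphabet, and dates are longer with digit-like internal
  structure, so a tagger has a learnable lexical+contextual signal.

Tokens are closed-alphabet pseudo-tokens (``w017``, ``p03``, ``d7``, ...) —
no real names or places appear anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import TextIO

import numpy as np

from .corpus import (
    PHI_CATEGORIES,
    Corpus,
    EntitySpan,
    LabeledSentence,
    spans_to_bio,
)

#: normalized original-annotation proportions of the emulated corpus
DEFAULT_PROPORTIONS: dict[str, float] = {
    "PER": 1448 / 5609,
    "LOC": 302 / 5609,
    "ORG": 846 / 5609,
    "DAT": 3013 / 5609,
}

#: per-category (min, max) mention length in tokens; dates run longer
MENTION_LENGTHS: dict[str, tuple[int, int]] = {
    "PER": (2, 3),
    "LOC": (2, 4),
    "ORG": (3, 5),
    "DAT": (4, 8),
}

# sub-alphabet sizes per category: small pools make mentions recur across
# sentences, which mention replacement and the tagger both rely on
_POOL_SIZES = {"PER": 30, "LOC": 15, "ORG": 20, "DAT": 10}


@dataclass
class GeneratorSpec:
    n_sentences: int = 500
    length_range: tuple[int, int] = (8, 30)
    entity_density: float = 1.2  # expected entities per non-sparse sentence
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    sparse_fraction: float = 0.3  # sentences forced to be entity-free
    vocab_size: int = 150  # context (O-tag) pseudo-token inventory
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if self.entity_density < 0:
            raise ValueError("entity density must be >= 0")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length range {self.length_range}")
        # a sentence must be able to host its expected entities
        max_mention = max(b for _, b in MENTION_LENGTHS.values())
        if self.entity_density * (max_mention + 1) > hi:
            raise ValueError(
                "entity density infeasible for the sentence length range"
            )


def category_mention_pool(category: str) -> list[tuple[str, ...]]:
    """The closed inventory of gold mentions the generator draws from."""
    prefix = category[0].lower()
    n = _POOL_SIZES[category]
    lo, hi = MENTION_LENGTHS[category]
    pool: list[tuple[str, ...]] = []
    # deterministic inventory: derived from the category alone, not the seed,
    # so surrogate disjointness can be checked against a fixed set
    import zlib

    rng = np.random.default_rng(zlib.crc32(category.encode()) % (2**31))
    alphabet = [f"{prefix}{i:02d}" for i in range(n)]
    for m in range(n):
        length = int(rng.integers(lo, hi + 1))
        mention = tuple(alphabet[int(rng.integers(0, n))] for _ in range(length))
        if category == "DAT":
            # digit-like internal structure: alternate digit/separator tokens
            mention = tuple(
                f"d{rng.integers(0, 10)}" if j % 2 == 0 else "sep"
                for j in range(length)
            )
        pool.append(mention)
    # dedupe, keep order
    seen, out = set(), []
    for mention in pool:
        if mention not in seen:
            seen.add(mention)
            out.append(mention)
    return out


def generate_corpus(spec: GeneratorSpec) -> Corpus:
    """Draw a seeded corpus of valid BIO sentences matching ``spec``.

    Entity categories are multinomial in ``spec.proportions``; a
    ``sparse_fraction`` of sentences carries no entities at all; the rest
    hold Poisson(density) entities (at least one), placed left-to-right with
    O-token gaps.
    """
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.proportions)
    probs = np.array([spec.proportions[c] for c in cats])
    pools = {c: category_mention_pool(c) for c in cats}
    context = [f"w{i:03d}" for i in range(spec.vocab_size)]
    lo, hi = spec.length_range
    sentences: list[LabeledSentence] = []
    for _ in range(spec.n_sentences):
        length = int(rng.integers(lo, hi + 1))
        sparse = rng.random() < spec.sparse_fraction or spec.entity_density == 0
        n_entities = 0
        if not sparse:
            n_entities = max(1, int(rng.poisson(spec.entity_density)))
        tokens: list[str] = []
        spans: list[EntitySpan] = []
        for _ in range(n_entities):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            mention = pools[cat][int(rng.integers(0, len(pools[cat])))]
            if len(tokens) + len(mention) + 1 > length:
                break
            # at least one O token between consecutive entities
            gap = int(rng.integers(1, 4))
            for _ in range(gap):
                if len(tokens) + len(mention) + 1 > length:
                    break
                tokens.append(context[int(rng.integers(0, len(context)))])
            if len(tokens) + len(mention) > length:
                break
            start = len(tokens)
            tokens.extend(mention)
            spans.append(EntitySpan(start, start + len(mention), cat))
        while len(tokens) < length:
            tokens.append(context[int(rng.integers(0, len(context)))])
        sentences.append(LabeledSentence(tokens, spans_to_bio(length, spans)))
    return Corpus(sentences)


@dataclass
class SurrogatePool:
    """Per-category replacement mentions, disjoint from all gold mentions."""

    mentions: dict[str, list[tuple[str, ...]]]

    def sample(self, category: str, rng: np.random.Generator) -> tuple[str, ...]:
        pool = self.mentions.get(category)
        if not pool:
            raise KeyError(f"no surrogates for category {category}")
        return pool[int(rng.integers(0, len(pool)))]


def make_surrogates(size_per_category: int = 20, seed: int = 0) -> SurrogatePool:
    """Build seeded surrogate mentions in a namespace no gold mention uses."""
    rng = np.random.default_rng(seed)
    mentions: dict[str, list[tuple[str, ...]]] = {}
    for cat in PHI_CATEGORIES:
        lo, hi = MENTION_LENGTHS[cat]
        pool: list[tuple[str, ...]] = []
        seen: set[tuple[str, ...]] = set()
        while len(pool) < size_per_category:
            length = int(rng.integers(lo, hi + 1))
            mention = tuple(
                f"x{cat.lower()}{rng.integers(0, 100):02d}" for _ in range(length)
            )
            if mention not in seen:
                seen.add(mention)
                pool.append(mention)
        mentions[cat] = pool
    return SurrogatePool(mentions)


def write_manifest(spec: GeneratorSpec, corpus: Corpus, stream: TextIO) -> None:
    """Record the generating spec, seed and realized counts next to the data."""
    payload = {
        "spec": asdict(spec),
        "n_sentences": len(corpus),
        "entity_counts": corpus.entity_counts(),
    }
    json.dump(payload, stream, indent=1)
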