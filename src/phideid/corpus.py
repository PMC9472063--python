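"""Corpus data model for PHI tagging: BIO tags, entity spans, CoNLL I/O.

The deidentification task is cast as named-entity recognition over four
protected-information categories — personal names (PER), locations (LOC),
organizations (ORG) and dates (DAT) — annotated with the strict BIO scheme:
``B-<cat>`` opens an entity, ``I-<cat>`` continues it, ``O`` marks
everything else.  Sentences are sequences of surface units; by default one
unit is one character (Chinese clinical text has no word delimiters), with
whitespace tokenization available for Latin-script material.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

PHI_CATEGORIES: tuple[str, ...] = ("PER", "LOC", "ORG", "DAT")
PAD, UNK = "<pad>", "<unk>"


class BioValidationError(ValueError):
    """A tag sequence violates the BIO dependency rules."""


class ConllParseError(ValueError):
    """A CoNLL-style stream is malformed."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open token span [start, end) carrying a PHI category."""

    start: int
    end: int
    category: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span bounds ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LabeledSentence:
    """Tokens plus a parallel, valid BIO tag sequence."""

    tokens: list[str]
    tags: list[str]
    source: str = "original"

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def entities(self) -> list[EntitySpan]:
        return bio_to_spans(self.tags)

    def mention(self, span: EntitySpan) -> tuple[str, ...]:
        return tuple(self.tokens[span.start : span.end])


@dataclass
class Corpus:
    """A list of labeled sentences with shared token/label vocabularies."""

    sentences: list[LabeledSentence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Corpus(self.sentences[i])
        return self.sentences[i]

    def label_vocab(self, categories: Sequence[str] | None = None) -> list[str]:
        """Ordered BIO label set: O first, then B-/I- per category."""
        if categories is None:
            cats = sorted(
                {t[2:] for s in self.sentences for t in s.tags if t != "O"}
            )
        else:
            cats = list(categories)
        labels = ["O"]
        for c in cats:
            labels += [f"B-{c}", f"I-{c}"]
        return labels

    def token_vocab(self, min_count: int = 1) -> list[str]:
        """Ordered surface vocabulary with reserved PAD/UNK entries."""
        counts: dict[str, int] = {}
        for s in self.sentences:
            for tok in s.tokens:
                counts[tok] = counts.get(tok, 0) + 1
        kept = [t for t, c in sorted(counts.items()) if c >= min_count]
        return [PAD, UNK] + kept

    def entity_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(PHI_CATEGORIES, 0)
        for s in self.sentences:
            for span in s.entities:
                counts[span.category] = counts.get(span.category, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# BIO scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BioViolation:
    position: int
    rule: str
    message: str


def spans_to_bio(length: int, spans: Sequence[EntitySpan]) -> list[str]:
    """Expand entity spans into a BIO tag sequence of ``length`` tokens.

    Spans must be non-overlapping and lie within ``[0, length)``.
    """
    tags = ["O"] * length
    prev_end = -1
    for span in sorted(spans):
        if span.end > length:
            raise ValueError(f"span {span} exceeds sentence length {length}")
        if span.start < prev_end:
            raise ValueError(f"span {span} overlaps a preceding span")
        prev_end = span.end
        tags[span.start] = f"B-{span.category}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.category}"
    return tags


def validate_bio(tags: Sequence[str]) -> list[BioViolation]:
    """Check the BIO dependency rules; an empty list means the sequence is valid.

    Rules: a sentence must not open with I-; I- must not follow O; and a
    continuation tag must carry the same category as the tag it continues
    (``B-PER I-ORG`` is invalid).
    """
    violations: list[BioViolation] = []
    prev = "O"
    for i, tag in enumerate(tags):
        if tag == "O":
            prev = tag
            continue
        if len(tag) < 3 or tag[1] != "-" or tag[0] not in "BI":
            violations.append(BioViolation(i, "unknown-tag", f"malformed tag {tag!r}"))
            prev = "O"
            continue
        if tag[0] == "I":
            if prev == "O":
                rule = "initial-I" if i == 0 else "I-after-O"
                what = "sentence-initial I- tag" if i == 0 else f"{tag} follows O"
                violations.append(BioViolation(i, rule, what))
            elif prev[2:] != tag[2:]:
                violations.append(
                    BioViolation(
                        i,
                        "category-switch",
                        f"category mismatch at position {i}: {prev} -> {tag}",
                    )
                )
        prev = tag
    return violations


def bio_to_spans(tags: Sequence[str]) -> list[EntitySpan]:
    """Collapse a valid BIO sequence into entity spans (inverse of spans_to_bio)."""
    violations = validate_bio(tags)
    if violations:
        v = violations[0]
        raise BioValidationError(f"position {v.position}: {v.message} [{v.rule}]")
    spans: list[EntitySpan] = []
    start, cat = None, None
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, cat))
            start, cat = i, tag[2:]
        elif tag == "O":
            if start is not None:
                spans.append(EntitySpan(start, i, cat))
            start, cat = None, None
    if start is not None:
        spans.append(EntitySpan(start, len(tags), cat))
    return spans


# ---------------------------------------------------------------------------
# CoNLL-style two-column I/O
# ---------------------------------------------------------------------------

def read_conll(stream: TextIO | str, on_invalid: str = "error") -> Corpus:
    """Read a two-column (token, tag) file; blank lines separate sentences.

    ``on_invalid`` controls BIO violations in the input: ``"error"`` raises,
    ``"repair"`` rewrites offending tags to ``O`` with a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if on_invalid not in ("error", "repair"):
        raise ValueError(f"on_invalid must be 'error' or 'repair', got {on_invalid!r}")
    sentences: list[LabeledSentence] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush(lineno: int):
        if not tokens:
            return
        violations = validate_bio(tags)
        if violations:
            if on_invalid == "error":
                v = violations[0]
                raise BioValidationError(
                    f"invalid BIO ending at line {lineno}: "
                    f"position {v.position}: {v.message} [{v.rule}]"
                )
            for v in violations:
                tags[v.position] = "O"
            warnings.warn(f"repaired {len(violations)} invalid BIO tag(s) to O")
        sentences.append(LabeledSentence(list(tokens), list(tags)))
        tokens.clear()
        tags.clear()

    lineno = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        cols = line.split()
        if len(cols) != 2:
            raise ConllParseError(
                f"line {lineno}: expected 2 columns, got {len(cols)}: {line!r}"
            )
        tokens.append(cols[0])
        tags.append(cols[1])
    flush(lineno + 1)
    return Corpus(sentences)


def write_conll(corpus: Corpus, stream: TextIO) -> None:
    """Write the canonical two-column form (token TAB tag, blank-line separated)."""
    for sentence in corpus:
        for tok, tag in zip(sentence.tokens, sentence.tags):
            stream.write(f"{tok}\t{tag}\n")
        stream.write("\n")


def corpus_to_conll(corpus: Corpus) -> str:
    buf = io.StringIO()
    write_conll(corpus, buf)
    return buf.getvalue()


def save_vocab(vocab: list[str], stream: TextIO) -> None:
    json.dump({"entries": vocab}, stream, ensure_ascii=False, indent=1)


def load_vocab(stream: TextIO) -> list[str]:
    return json.load(stream)["entries"]


# ---------------------------------------------------------------------------
# Deterministic splitting
# ---------------------------------------------------------------------------

def split_corpus(
    corpus: Corpus,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[Corpus, ...]:
    """Randomly partition sentences into train/eval/test at the given ratios.

    The partition is a disjoint cover, each part within one sentence of its
    exact share, and is deterministic for a fixed seed.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError(f"all split ratios must be positive, got {ratios}")
    total = float(sum(ratios))
    n = len(corpus)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # largest-remainder apportionment keeps every size within 1 of ratio*n
    exact = [r / total * n for r in ratios]
    sizes = [int(e) for e in exact]
    remainders = sorted(
        range(len(ratios)), key=lambda i: exact[i] - sizes[i], reverse=True
    )
    for i in range(n - sum(sizes)):
        sizes[remainders[i % len(ratios)]] += 1
    if min(sizes) == 0:
        warnings.warn(
            f"corpus of {n} sentences leaves an empty part for ratios {tuple(ratios)}"
        )
    parts: list[Corpus] = []
    offset = 0
    for size in sizes:
        idx = sorted(order[offset : offset + size])
        parts.append(Corpus([corpus.sentences[i] for i in idx]))
        offset += size
    return tuple(parts)
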