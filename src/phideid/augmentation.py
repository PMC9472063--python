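"""Hybrid data augmentation for sequence labeling: DAGA + mention replacement.

Generation-based augmentation (DAGA) linearizes each labeled sentence into a
single stream where every non-O token is immediately preceded by its tag
marker (``B-PER p03 I-PER p11 w042 ...``), trains a next-token language
model on these streams, samples fresh streams from it, and de-linearizes
them back into labeled sentences, rejecting any stream that does not decode
into a valid BIO sentence.  Because labels and words are generated jointly,
the synthesized sentences follow the tag-context distribution of the
training data instead of perturbing it.

Mention replacement (MR) attacks entity sparsity directly: each entity in a
sentence is independently replaced, with probability ``p`` (default 0.5),
by another mention of the same category drawn from the training pool, tags
re-expanded to the new mention length.

The hybrid set is the union: original + DAGA + MR, with per-sentence
provenance; evaluation and test sets are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, parameter
from .corpus import (
    Corpus,
    EntitySpan,
    LabeledSentence,
    spans_to_bio,
    validate_bio,
)

BOS, EOS = "<s>", "</s>"


@dataclass
class AugmentationConfig:
    daga_sample_count: int | None = None  # default: 2x corpus size
    mr_pass_count: int = 2
    replacement_prob: float = 0.5
    max_generated_length: int = 60
    temperature: float = 1.0
    lm_hidden_dim: int = 48
    lm_epochs: int = 30
    lm_lr: float = 5e-3
    max_attempt_factor: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.replacement_prob <= 1.0:
            raise ValueError("replacement probability must lie in [0, 1]")
        if self.mr_pass_count < 0 or (
            self.daga_sample_count is not None and self.daga_sample_count < 0
        ):
            raise ValueError("augmentation counts must be >= 0")


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------

def linearize(sentence: LabeledSentence) -> list[str]:
    """Mix tag markers into the token stream: marker before each non-O token."""
    violations = validate_bio(sentence.tags)
    if violations:
        raise ValueError(f"cannot linearize invalid BIO sentence: {violations[0]}")
    stream: list[str] = []
    for tok, tag in zip(sentence.tokens, sentence.tags):
        if tag != "O":
            stream.append(tag)
        stream.append(tok)
    return stream


@dataclass(frozen=True)
class Rejection:
    reason: str
    position: int


def delinearize(stream: list[str]) -> LabeledSentence | Rejection:
    """Reconstruct (tokens, tags) from a sampled stream, or reject it.

    Reasons: ``dangling-marker`` (marker followed by a marker or end of
    stream), ``invalid-bio`` (decoded tags break the BIO rules, e.g. a
    stream opening with an I- marker), ``empty``.
    """
    tokens: list[str] = []
    tags: list[str] = []
    i = 0
    while i < len(stream):
        item = stream[i]
        if _is_marker(item):
            if i + 1 >= len(stream) or _is_marker(stream[i + 1]):
                return Rejection("dangling-marker", i)
            tokens.append(stream[i + 1])
            tags.append(item)
            i += 2
        else:
            tokens.append(item)
            tags.append("O")
            i += 1
    if not tokens:
        return Rejection("empty", 0)
    if validate_bio(tags):
        return Rejection("invalid-bio", validate_bio(tags)[0].position)
    return LabeledSentence(tokens, tags, source="daga")


def _is_marker(item: str) -> bool:
    return len(item) > 2 and item[1] == "-" and item[0] in "BI"


# ---------------------------------------------------------------------------
# Generative language model over linearized streams
# ---------------------------------------------------------------------------

class StreamLm:
    """Single-layer recurrent next-token model over the joint vocabulary.

    Embeddings ``e_t`` feed a recurrence ``h_t = tanh(M e_t + U h_{t-1} + b)``
    whose state is projected to a softmax over the vocabulary (markers,
    surface tokens, and the boundary symbols).
    """

    def __init__(self, vocab: list[str], hidden_dim: int = 48, seed: int = 0):
        if len(vocab) < 2:
            raise ValueError("LM vocabulary must contain at least 2 symbols")
        self.vocab = list(vocab)
        self.index = {w: i for i, w in enumerate(self.vocab)}
        v, d = len(self.vocab), hidden_dim
        rng = np.random.default_rng(seed)
        self.emb = parameter(rng.normal(0, 0.1, size=(v, d)))
        self.m = parameter(rng.normal(0, 0.1, size=(d, d)))  # input weight M
        self.u = parameter(rng.normal(0, 0.1, size=(d, d)))  # state weight
        self.b = parameter(np.zeros(d))
        self.out_w = parameter(rng.normal(0, 0.1, size=(d, v)))
        self.out_b = parameter(np.zeros(v))

    def parameters(self) -> list[Tensor]:
        return [self.emb, self.m, self.u, self.b, self.out_w, self.out_b]

    def _step(self, ids: np.ndarray, h: Tensor) -> tuple[Tensor, Tensor]:
        e = self.emb[ids]
        h = (e @ self.m + h @ self.u + self.b).tanh()
        return h, h @ self.out_w + self.out_b

    def sequence_nll(self, batch_ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean next-token negative log-likelihood over a padded id batch."""
        b, length = batch_ids.shape
        h = Tensor(np.zeros((b, self.m.shape[0])))
        total: Tensor | None = None
        for t in range(length - 1):
            h, logits = self._step(batch_ids[:, t], h)
            logp = logits.log_softmax(axis=-1)
            picked = logp.gather_last(batch_ids[:, t + 1][:, None]).reshape(b)
            step = -(picked * Tensor(mask[:, t + 1].astype(float))).sum()
            total = step if total is None else total + step
        return total / max(mask[:, 1:].sum(), 1.0)

    def next_distribution(self, prefix: list[str]) -> np.ndarray:
        """Probability over the vocabulary of the next symbol after ``prefix``."""
        h = np.zeros(self.m.shape[0])
        logits = None
        for w in prefix:
            e = self.emb.data[self.index[w]]
            h = np.tanh(e @ self.m.data + h @ self.u.data + self.b.data)
            logits = h @ self.out_w.data + self.out_b.data
        if logits is None:
            raise ValueError("prefix must contain at least the start symbol")
        z = logits - logits.max()
        p = np.exp(z)
        return p / p.sum()

    def sample(
        self,
        rng: np.random.Generator,
        max_len: int,
        temperature: float = 1.0,
    ) -> list[str]:
        """Draw one stream, symbol by symbol, until EOS or ``max_len``."""
        h = np.zeros(self.m.shape[0])
        prev = self.index[BOS]
        out: list[str] = []
        for _ in range(max_len):
            e = self.emb.data[prev]
            h = np.tanh(e @ self.m.data + h @ self.u.data + self.b.data)
            logits = h @ self.out_w.data + self.out_b.data
            logits[self.index[BOS]] = -np.inf  # never re-emit the start symbol
            if temperature <= 1e-6:
                nxt = int(np.argmax(logits))
            else:
                z = logits / temperature
                z = z - np.nanmax(z)
                p = np.exp(z)
                p[~np.isfinite(p)] = 0.0
                p = p / p.sum()
                nxt = int(rng.choice(len(p), p=p))
            if nxt == self.index[EOS]:
                break
            out.append(self.vocab[nxt])
            prev = nxt
        return out


def train_lm(
    corpus: Corpus, config: AugmentationConfig, seed: int | None = None
) -> StreamLm:
    """Fit the stream LM by maximizing next-token log-likelihood on the
    linearized training sentences (mini-batch Adam)."""
    if len(corpus) == 0:
        raise ValueError("cannot train a language model on an empty corpus")
    seed = config.seed if seed is None else seed
    streams = [[BOS] + linearize(s) + [EOS] for s in corpus]
    vocab = [BOS, EOS]
    seen = set(vocab)
    for stream in streams:
        for w in stream:
            if w not in seen:
                seen.add(w)
                vocab.append(w)
    lm = StreamLm(vocab, hidden_dim=config.lm_hidden_dim, seed=seed)
    opt = Adam(lm.parameters(), lr=config.lm_lr)
    rng = np.random.default_rng(seed + 1)
    batch_size = 16
    for _ in range(config.lm_epochs):
        order = rng.permutation(len(streams))
        for ofs in range(0, len(order), batch_size):
            chunk = [streams[i] for i in order[ofs : ofs + batch_size]]
            max_len = max(len(c) for c in chunk)
            ids = np.zeros((len(chunk), max_len), dtype=np.int64)
            mask = np.zeros((len(chunk), max_len), dtype=np.int64)
            for r, stream in enumerate(chunk):
                ids[r, : len(stream)] = [lm.index[w] for w in stream]
                mask[r, : len(stream)] = 1
            loss = lm.sequence_nll(ids, mask)
            if not np.isfinite(loss.item()):
                raise RuntimeError("language model training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return lm


# ---------------------------------------------------------------------------
# DAGA sampling
# ---------------------------------------------------------------------------

@dataclass
class DagaStats:
    requested: int = 0
    accepted: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1


def daga_augment(
    corpus: Corpus,
    config: AugmentationConfig,
    lm: StreamLm | None = None,
) -> tuple[list[LabeledSentence], DagaStats]:
    """Sample new labeled sentences from a stream LM trained on ``corpus``.

    Every accepted sentence decodes to valid BIO; rejects are counted by
    reason.  Gives up (with a warning) after ``max_attempt_factor`` times the
    requested count of draws.
    """
    import warnings

    n = config.daga_sample_count
    if n is None:
        n = 2 * len(corpus)
    stats = DagaStats(requested=n)
    if n == 0:
        return [], stats
    if lm is None:
        lm = train_lm(corpus, config)
    rng = np.random.default_rng(config.seed + 17)
    accepted: list[LabeledSentence] = []
    attempts = 0
    while len(accepted) < n and attempts < config.max_attempt_factor * n:
        attempts += 1
        stream = lm.sample(rng, config.max_generated_length, config.temperature)
        result = delinearize(stream)
        if isinstance(result, Rejection):
            stats.reject(result.reason)
            continue
        accepted.append(result)
    if not accepted:
        warnings.warn("DAGA produced no valid sentences within the attempt budget")
    stats.accepted = len(accepted)
    return accepted, stats


# ---------------------------------------------------------------------------
# Mention replacement
# ---------------------------------------------------------------------------

def build_mention_pool(corpus: Corpus) -> dict[str, list[tuple[str, ...]]]:
    """Distinct mentions per category observed in the training set."""
    pool: dict[str, set[tuple[str, ...]]] = {}
    for sentence in corpus:
        for span in sentence.entities:
            pool.setdefault(span.category, set()).add(sentence.mention(span))
    return {c: sorted(ms) for c, ms in pool.items()}


def mention_replace(
    corpus: Corpus,
    config: AugmentationConfig,
    pool: dict[str, list[tuple[str, ...]]] | None = None,
) -> list[LabeledSentence]:
    """One replacement pass: per entity, an independent Bernoulli(p) decision
    to swap it for another same-category training mention.

    When the decision fires and the category pool holds more than one
    mention, the replacement is drawn uniformly from the pool excluding the
    current mention; a singleton pool keeps the entity unchanged.
    """
    if pool is None:
        pool = build_mention_pool(corpus)
    rng = np.random.default_rng(config.seed + 29)
    out: list[LabeledSentence] = []
    for sentence in corpus:
        tokens: list[str] = []
        spans: list[EntitySpan] = []
        cursor = 0
        for span in sentence.entities:
            tokens.extend(sentence.tokens[cursor : span.start])
            mention = sentence.mention(span)
            if rng.random() < config.replacement_prob:
                candidates = [m for m in pool.get(span.category, []) if m != mention]
                if candidates:
                    mention = candidates[int(rng.integers(0, len(candidates)))]
            start = len(tokens)
            tokens.extend(mention)
            spans.append(EntitySpan(start, start + len(mention), span.category))
            cursor = span.end
        tokens.extend(sentence.tokens[cursor:])
        out.append(
            LabeledSentence(tokens, spans_to_bio(len(tokens), spans), source="mr")
        )
    return out


# ---------------------------------------------------------------------------
# Hybrid combination
# ---------------------------------------------------------------------------

@dataclass
class AugmentationSummary:
    """Entity counts per category and source (original / daga / mr / total)."""

    rows: dict[str, dict[str, int]]

    def to_csv(self, stream) -> None:
        stream.write("category,original,daga,mr,total\n")
        for cat, row in self.rows.items():
            stream.write(
                f"{cat},{row['original']},{row['daga']},{row['mr']},{row['total']}\n"
            )


def hybrid_augment(
    corpus: Corpus, config: AugmentationConfig
) -> tuple[Corpus, AugmentationSummary, DagaStats]:
    """Original + DAGA-generated + MR-modified training sentences.

    Only ever applied to a training split; provenance is retained on every
    sentence (``source`` in {original, daga, mr}).
    """
    daga_sentences, stats = daga_augment(corpus, config)
    mr_sentences: list[LabeledSentence] = []
    for i in range(config.mr_pass_count):
        pass_config = AugmentationConfig(
            **{**config.__dict__, "seed": config.seed + 1000 * (i + 1)}
        )
        mr_sentences.extend(mention_replace(corpus, pass_config))
    combined = Corpus(list(corpus.sentences) + daga_sentences + mr_sentences)

    def counts(sentences) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in sentences:
            for span in s.entities:
                out[span.category] = out.get(span.category, 0) + 1
        return out

    orig_c = counts(corpus.sentences)
    daga_c = counts(daga_sentences)
    mr_c = counts(mr_sentences)
    cats = sorted(set(orig_c) | set(daga_c) | set(mr_c))
    rows = {
        cat: {
            "original": orig_c.get(cat, 0),
            "daga": daga_c.get(cat, 0),
            "mr": mr_c.get(cat, 0),
            "total": orig_c.get(cat, 0) + daga_c.get(cat, 0) + mr_c.get(cat, 0),
        }
        for cat in cats
    }
    return combined, AugmentationSummary(rows), stats
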