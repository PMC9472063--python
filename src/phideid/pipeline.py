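"""End-to-end tagging pipeline: joint encoder+CRF training, constrained
prediction, surrogate deidentification and annotation bootstrapping.

The tagger couples the transformer encoder (emission scores) with the
linear-chain CRF (transition scores) and is trained end-to-end by
minimizing the CRF negative log-likelihood of the gold tag paths.
Prediction runs BIO-constrained Viterbi, so outputs can never contain an
illegal transition.  Deidentification replaces every predicted PHI span
with a same-category surrogate mention and keeps a reversible log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .autodiff import Adam
from .corpus import Corpus, LabeledSentence
from .crf import CrfHead, log_partition, viterbi
from .encoder import (
    EncoderConfig,
    TransformerEncoder,
    tokenize,
    vocab_fingerprint,
)
from .evaluation import evaluate
from .synthetic import SurrogatePool


@dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 32
    lr: float = 5e-3
    seed: int = 0


@dataclass
class TaggerModel:
    """Everything needed to tag new text: encoder, CRF, vocabularies."""

    encoder: TransformerEncoder
    crf: CrfHead
    token_vocab: list[str]
    label_vocab: list[str]

    def fingerprint(self) -> dict[str, int]:
        return {
            "token_vocab": vocab_fingerprint(self.token_vocab),
            "label_vocab": vocab_fingerprint(self.label_vocab),
        }

    # -- persistence: single .npz checkpoint ---------------------------------
    def save(self, path: str) -> None:
        arrays = self.encoder.state_arrays()
        arrays["crf.transitions"] = self.crf.transitions.data
        meta = {
            "config": asdict(self.encoder.config),
            "token_vocab": self.token_vocab,
            "label_vocab": self.label_vocab,
            "fingerprint": self.fingerprint(),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str, expect_token_vocab: list[str] | None = None) -> "TaggerModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        if expect_token_vocab is not None and vocab_fingerprint(
            expect_token_vocab
        ) != meta["fingerprint"]["token_vocab"]:
            raise ValueError("checkpoint token vocabulary does not match")
        config = EncoderConfig(**meta["config"])
        config.ffn_dim = meta["config"]["ffn_dim"]
        encoder = TransformerEncoder(config, n_labels=len(meta["label_vocab"]))
        encoder.load_state_arrays(arrays)
        crf = CrfHead(meta["label_vocab"])
        crf.transitions.data = np.array(arrays["crf.transitions"])
        return cls(encoder, crf, meta["token_vocab"], meta["label_vocab"])


def _encode_tags(
    corpus_or_sents: Sequence[LabeledSentence], label_vocab: list[str], max_len: int
) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(label_vocab)}
    n = len(corpus_or_sents)
    tags = np.zeros((n, max_len), dtype=np.int64)
    for r, s in enumerate(corpus_or_sents):
        ids = [index[t] for t in s.tags][:max_len]
        tags[r, : len(ids)] = ids
    return tags


@dataclass
class EpochRecord:
    epoch: int
    train_nll: float
    eval_micro_f1: float


def make_tagger(
    train_corpus: Corpus, encoder_config: EncoderConfig, seed: int = 0
) -> TaggerModel:
    """Fresh randomly-initialized tagger with vocabularies from the train set."""
    token_vocab = train_corpus.token_vocab()
    label_vocab = train_corpus.label_vocab()
    config = EncoderConfig(**{**asdict(encoder_config), "vocab_size": len(token_vocab), "seed": seed})
    encoder = TransformerEncoder(config, n_labels=len(label_vocab))
    crf = CrfHead(label_vocab, seed=seed)
    return TaggerModel(encoder, crf, token_vocab, label_vocab)


def train_tagger(
    train_corpus: Corpus,
    eval_corpus: Corpus | None,
    encoder_config: EncoderConfig,
    train_config: TrainConfig | None = None,
    model: TaggerModel | None = None,
) -> tuple[TaggerModel, list[EpochRecord]]:
    """Minimize mean CRF NLL over the training set; track eval micro-F1.

    Returns the checkpoint with the best eval micro-F1 (final epoch when no
    eval corpus is given) and the per-epoch trace.  Deterministic per seed.
    """
    tc = train_config or TrainConfig()
    if model is None:
        model = make_tagger(train_corpus, encoder_config, seed=tc.seed)
    return _fit(model, train_corpus, eval_corpus, tc)


def _fit(
    model: TaggerModel,
    train_corpus: Corpus,
    eval_corpus: Corpus | None,
    tc: TrainConfig,
) -> tuple[TaggerModel, list[EpochRecord]]:
    encoder, crf = model.encoder, model.crf
    params = encoder.parameters() + crf.parameters()
    opt = Adam(params, lr=tc.lr)
    rng = np.random.default_rng(tc.seed)
    sentences = train_corpus.sentences
    max_len = encoder.config.max_len
    trace: list[EpochRecord] = []
    best_f1, best_state = -1.0, None
    encoder.training = True
    for epoch in range(tc.epochs):
        order = rng.permutation(len(sentences))
        total_nll, n_batches = 0.0, 0
        for ofs in range(0, len(order), tc.batch_size):
            chunk = [sentences[i] for i in order[ofs : ofs + tc.batch_size]]
            batch = tokenize([s.tokens for s in chunk], model.token_vocab, max_len)
            gold = _encode_tags(chunk, model.label_vocab, max_len)
            _, emissions = encoder.forward(batch)
            loss = crf.nll(emissions, gold, batch.lengths)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: NLL={loss.item()}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_nll += loss.item()
            n_batches += 1
        encoder.training = False
        f1 = float("nan")
        if eval_corpus is not None and len(eval_corpus) > 0:
            f1 = evaluate(eval_corpus, predict(model, [s.tokens for s in eval_corpus])).micro.f1
            if f1 >= best_f1:
                best_f1 = f1
                best_state = (
                    {k: v.copy() for k, v in encoder.state_arrays().items()},
                    crf.transitions.data.copy(),
                )
        encoder.training = True
        trace.append(EpochRecord(epoch, total_nll / max(n_batches, 1), f1))
    encoder.training = False
    if best_state is not None:
        encoder.load_state_arrays(best_state[0])
        crf.transitions.data = best_state[1]
    return model, trace


def predict(model: TaggerModel, sentences: Sequence[Sequence[str]]) -> Corpus:
    """Constrained Viterbi tagging; every output is a valid BIO sentence.

    Tokens beyond the encoder's max_len keep the O tag (the encoder never
    sees them); shorter sentences decode over their true length.
    """
    if not sentences:
        return Corpus([])
    max_len = model.encoder.config.max_len
    out: list[LabeledSentence] = []
    batch_size = 64
    for ofs in range(0, len(sentences), batch_size):
        chunk = [list(s) for s in sentences[ofs : ofs + batch_size]]
        batch = tokenize(chunk, model.token_vocab, max_len)
        _, emissions = model.encoder.forward(batch)
        paths = model.crf.decode(emissions.data, batch.lengths, constrained=True)
        for sent, path in zip(chunk, paths):
            tags = [model.label_vocab[i] for i in path]
            tags += ["O"] * (len(sent) - len(tags))  # truncated tail
            out.append(LabeledSentence(sent, tags, source="predicted"))
    return Corpus(out)


def path_confidence(model: TaggerModel, sentence: Sequence[str]) -> float:
    """Normalized Viterbi path probability exp(best_score - logZ) in (0, 1]."""
    batch = tokenize([list(sentence)], model.token_vocab, model.encoder.config.max_len)
    _, emissions = model.encoder.forward(batch)
    length = int(batch.lengths[0])
    em = emissions.data[0, :length]
    trans = model.crf.transitions.data
    _, best = viterbi(em, trans, model.crf.mask)
    logz = log_partition(em, trans)
    return float(np.exp(min(best - logz, 0.0)))


@dataclass
class Replacement:
    sentence_index: int
    start: int
    end: int
    category: str
    original: tuple[str, ...]
    surrogate: tuple[str, ...]


def deidentify(
    model: TaggerModel,
    sentences: Sequence[Sequence[str]],
    surrogates: SurrogatePool,
    seed: int = 0,
) -> tuple[list[list[str]], list[Replacement]]:
    """Replace every predicted PHI span with a same-category surrogate.

    Surrogates may change token counts; the replacement log carries enough
    information (positions in the redacted text, original mention) to invert
    the substitution.
    """
    rng = np.random.default_rng(seed)
    tagged = predict(model, sentences)
    for cat in {sp.category for s in tagged for sp in s.entities}:
        if cat not in surrogates.mentions:
            raise KeyError(f"surrogate pool lacks category {cat}")
    redacted: list[list[str]] = []
    log: list[Replacement] = []
    for i, sent in enumerate(tagged):
        tokens: list[str] = []
        cursor = 0
        for span in sent.entities:
            tokens.extend(sent.tokens[cursor : span.start])
            surrogate = surrogates.sample(span.category, rng)
            log.append(
                Replacement(
                    i,
                    len(tokens),
                    len(tokens) + len(surrogate),
                    span.category,
                    sent.mention(span),
                    surrogate,
                )
            )
            tokens.extend(surrogate)
            cursor = span.end
        tokens.extend(sent.tokens[cursor:])
        redacted.append(tokens)
    return redacted, log


def undo_deidentify(
    redacted: list[list[str]], log: list[Replacement]
) -> list[list[str]]:
    """Invert a deidentification pass using its replacement log."""
    out = [list(s) for s in redacted]
    by_sentence: dict[int, list[Replacement]] = {}
    for rep in log:
        by_sentence.setdefault(rep.sentence_index, []).append(rep)
    for i, reps in by_sentence.items():
        for rep in sorted(reps, key=lambda r: r.start, reverse=True):
            out[i][rep.start : rep.end] = list(rep.original)
    return out


def distill_tagger(
    teacher: TaggerModel,
    student_encoder_config: EncoderConfig,
    corpus: Corpus,
    steps: int = 150,
    batch_size: int = 16,
    lr: float = 5e-3,
    seed: int = 0,
) -> tuple[TaggerModel, list]:
    """Distill a compact student tagger from a trained teacher.

    The student encoder learns the teacher's attention maps, hidden states,
    embedding output and emission logits on the given sentences; the CRF
    transition matrix (the prediction layer) is copied from the teacher.
    """
    from .distillation import distill

    config = EncoderConfig(
        **{
            **asdict(student_encoder_config),
            "vocab_size": len(teacher.token_vocab),
            "max_len": teacher.encoder.config.max_len,
            "seed": seed,
        }
    )
    student_encoder, trace = distill(
        teacher.encoder,
        config,
        corpus,
        teacher.token_vocab,
        n_labels=len(teacher.label_vocab),
        steps=steps,
        batch_size=batch_size,
        lr=lr,
        seed=seed,
    )
    crf = CrfHead(teacher.label_vocab, seed=seed)
    crf.transitions.data = teacher.crf.transitions.data.copy()
    student = TaggerModel(
        student_encoder, crf, list(teacher.token_vocab), list(teacher.label_vocab)
    )
    return student, trace


@dataclass
class BootstrapResult:
    proposed: Corpus
    confidences: list[float]
    flagged: list[int]  # indices with confidence below the threshold


def bootstrap_annotate(
    mini_corpus: Corpus,
    unlabeled: Sequence[Sequence[str]],
    encoder_config: EncoderConfig,
    train_config: TrainConfig | None = None,
    confidence_threshold: float = 0.5,
) -> BootstrapResult:
    """Annotation bootstrapping: train on a small labeled seed set, predict on
    the unlabeled bulk, and flag low-confidence sentences for manual review.

    Confidence is the normalized Viterbi path probability; the flagged list
    grows monotonically with the threshold.
    """
    if len(mini_corpus) < 2:
        raise ValueError("mini corpus too small to build vocabularies")
    model, _ = train_tagger(mini_corpus, None, encoder_config, train_config)
    proposed = predict(model, unlabeled)
    confidences = [path_confidence(model, s) for s in unlabeled]
    flagged = [i for i, c in enumerate(confidences) if c < confidence_threshold]
    return BootstrapResult(proposed, confidences, flagged)
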