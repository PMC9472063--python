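"""Reproducible study-scale experiments over the synthetic corpora.

Each function sets up its own seeded inputs, runs one property or
directional comparison end to end through the package, and returns plain
numbers.  They back both the acceptance checks and the reproduction script;
problem sizes are chosen so the full set runs in minutes on one CPU.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .augmentation import AugmentationConfig, hybrid_augment, mention_replace, build_mention_pool
from .corpus import Corpus, split_corpus, validate_bio
from .crf import log_partition, sequence_score, viterbi
from .distillation import (
    TeacherStudentStates,
    distillation_losses,
    map_layers,
    ProjectionParams,
    teacher_entropy,
)
from .autodiff import parameter
from .encoder import EncoderConfig, tokenize
from .evaluation import evaluate
from .pipeline import (
    TrainConfig,
    _fit,
    distill_tagger,
    make_tagger,
    predict,
    train_tagger,
)
from .synthetic import GeneratorSpec, generate_corpus

#: encoder shapes used throughout the desk-scale experiments
TEACHER_SHAPE = dict(n_layers=4, hidden_dim=32, n_heads=2, ffn_dim=64, max_len=32)
STUDENT_SHAPE = dict(n_layers=2, hidden_dim=32, n_heads=2, ffn_dim=64, max_len=32)


def _enumerate_paths(emissions: np.ndarray, transitions: np.ndarray) -> np.ndarray:
    """Scores of every label path, straight from the definition."""
    length, k = emissions.shape
    scores = []
    for path in itertools.product(range(k), repeat=length):
        scores.append(sequence_score(emissions, transitions, path).total)
    return np.array(scores)


def crf_oracle_check(n_instances: int = 200, seed: int = 0) -> dict[str, float]:
    """Forward log-partition vs exhaustive enumeration; Viterbi vs argmax.

    Random instances with L <= 6 and K <= 5.  Returns the maximum absolute
    log-partition error and the number of Viterbi/argmax disagreements.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    mismatches = 0
    for _ in range(n_instances):
        length = int(rng.integers(1, 7))
        k = int(rng.integers(2, 6))
        em = rng.normal(size=(length, k))
        tr = rng.normal(size=(k + 2, k + 2))
        scores = _enumerate_paths(em, tr)
        logz_ref = float(np.logaddexp.reduce(scores))
        max_err = max(max_err, abs(log_partition(em, tr) - logz_ref))
        path, score = viterbi(em, tr)
        best = int(scores.argmax())
        ref_path = list(
            np.unravel_index(best, (k,) * length)
        )
        if path != [int(x) for x in ref_path] or abs(score - scores[best]) > 1e-9:
            mismatches += 1
    return {"max_log_partition_error": max_err, "viterbi_mismatches": mismatches}


def normalization_check(n_instances: int = 50, seed: int = 0) -> float:
    """Max deviation of sum_paths exp(score - logZ) from 1 on small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        length = int(rng.integers(1, 6))
        k = int(rng.integers(2, 5))
        em = rng.normal(size=(length, k))
        tr = rng.normal(size=(k + 2, k + 2))
        scores = _enumerate_paths(em, tr)
        total = np.exp(scores - log_partition(em, tr)).sum()
        worst = max(worst, abs(total - 1.0))
    return worst


def constrained_decoding_check(n_sentences: int = 1000, seed: int = 0) -> dict[str, int]:
    """Count BIO violations in constrained decodes of synthetic sentences.

    Uses an untrained (randomly initialized) tagger: its emissions carry no
    linguistic signal, so only the transition constraints keep the output
    legal — the hardest setting for the decoder.
    """
    corpus = generate_corpus(GeneratorSpec(n_sentences=n_sentences, seed=seed))
    model = make_tagger(corpus, EncoderConfig(**STUDENT_SHAPE), seed=seed)
    pred = predict(model, [s.tokens for s in corpus])
    violations = sum(len(validate_bio(s.tags)) for s in pred)
    return {"n_sentences": len(pred), "bio_violations": violations}


def distillation_floor_check(seed: int = 0) -> dict[str, float]:
    """Self-distillation fixture: student states identical to the teacher's."""
    from .encoder import TransformerEncoder

    corpus = generate_corpus(GeneratorSpec(n_sentences=20, length_range=(5, 12), seed=seed))
    vocab = corpus.token_vocab()
    teacher = TransformerEncoder(
        EncoderConfig(**{**TEACHER_SHAPE, "vocab_size": len(vocab), "seed": seed}),
        n_labels=9,
    )
    batch = tokenize([s.tokens for s in corpus.sentences[:8]], vocab, teacher.config.max_len)
    states, logits = teacher.forward(batch)
    ts = TeacherStudentStates(states, states, logits, logits)
    d = teacher.config.hidden_dim
    projections = ProjectionParams(parameter(np.eye(d)), parameter(np.eye(d)))
    _, logged = distillation_losses(
        ts, map_layers(teacher.config.n_layers, teacher.config.n_layers),
        projections, mask=batch.attention_mask,
    )
    floor = teacher_entropy(logits, batch.attention_mask)
    return {
        "l_tr": logged.l_tr,
        "l_emb": logged.l_emb,
        "l_pr_minus_entropy_floor": logged.l_pr - floor,
        "sum_identity_error": abs(logged.l_total - (logged.l_tr + logged.l_emb + logged.l_pr)),
    }


@dataclass
class BenefitResult:
    per_seed: list[tuple[float, float]]  # (treatment F1, control F1)

    @property
    def wins(self) -> int:
        return sum(a > b for a, b in self.per_seed)

    @property
    def mean_treatment(self) -> float:
        return float(np.mean([a for a, _ in self.per_seed]))

    @property
    def mean_control(self) -> float:
        return float(np.mean([b for _, b in self.per_seed]))


def distillation_benefit(
    seed: int = 0,
    n_sentences: int = 500,
    teacher_epochs: int = 8,
    distill_steps: int = 120,
    finetune_epochs: int = 1,
    n_seeds: int = 3,
) -> BenefitResult:
    """Distilled 2-layer student vs same-shape random-init student.

    A 4-layer teacher is trained on the synthetic training split; per seed, a
    student is distilled from it and a control student starts from random
    init, then both get the identical short task fine-tune.  Held-out
    entity-level micro-F1 decides each seed's comparison.
    """
    corpus = generate_corpus(GeneratorSpec(n_sentences=n_sentences, seed=seed))
    train, dev, test = split_corpus(corpus, (0.6, 0.2, 0.2), seed=seed)
    teacher, _ = train_tagger(
        train, dev, EncoderConfig(**TEACHER_SHAPE),
        TrainConfig(epochs=teacher_epochs, seed=seed),
    )
    test_tokens = [s.tokens for s in test]
    results = []
    for i in range(n_seeds):
        run_seed = seed + 100 + i
        scfg = EncoderConfig(**STUDENT_SHAPE)
        student, _ = distill_tagger(teacher, scfg, train, steps=distill_steps, seed=run_seed)
        ft = TrainConfig(epochs=finetune_epochs, seed=run_seed)
        student, _ = _fit(student, train, None, ft)
        f1_distilled = evaluate(test, predict(student, test_tokens)).micro.f1
        control = make_tagger(train, scfg, seed=run_seed)
        control, _ = _fit(control, train, None, ft)
        f1_control = evaluate(test, predict(control, test_tokens)).micro.f1
        results.append((f1_distilled, f1_control))
    return BenefitResult(results)


def mr_replacement_rate(
    p: float = 0.5, n_decisions: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Realized replacement fraction over exactly ``n_decisions`` entity decisions."""
    corpus = generate_corpus(
        GeneratorSpec(n_sentences=900, length_range=(8, 20), seed=seed, sparse_fraction=0.0)
    )
    pool = build_mention_pool(corpus)
    out = mention_replace(corpus, AugmentationConfig(replacement_prob=p, seed=seed), pool)
    decisions = replaced = 0
    for before, after in zip(corpus, out):
        for s_b, s_a in zip(before.entities, after.entities):
            if len(pool[s_b.category]) > 1:  # only these can visibly change
                decisions += 1
                replaced += before.mention(s_b) != after.mention(s_a)
            if decisions == n_decisions:
                break
        if decisions == n_decisions:
            break
    if decisions < n_decisions:
        raise RuntimeError(f"only {decisions} entity decisions generated")
    return {"decisions": decisions, "replaced_fraction": replaced / decisions}


def daga_validity_check(seed: int = 0, n_round_trip: int = 1000, n_generated: int = 200) -> dict[str, float]:
    """Round-trip identity on random valid sentences; validity of accepted samples."""
    from .augmentation import daga_augment, delinearize, linearize, Rejection

    corpus = generate_corpus(GeneratorSpec(n_sentences=n_round_trip, seed=seed))
    round_trip_failures = 0
    for s in corpus:
        back = delinearize(linearize(s))
        if isinstance(back, Rejection) or back.tokens != s.tokens or back.tags != s.tags:
            round_trip_failures += 1
    cfg = AugmentationConfig(daga_sample_count=n_generated, lm_epochs=10, seed=seed)
    train_part = Corpus(corpus.sentences[:200])
    generated, stats = daga_augment(train_part, cfg)
    invalid = sum(1 for s in generated if validate_bio(s.tags))
    return {
        "round_trip_failures": round_trip_failures,
        "generated": stats.accepted,
        "invalid_generated": invalid,
    }


def hybrid_benefit(
    seed: int = 0,
    n_sentences: int = 500,
    epochs: int = 5,
    n_seeds: int = 3,
) -> BenefitResult:
    """Tagger on the hybrid-augmented training set vs on a 50% raw subsample.

    The directional data-volume comparison: more (augmented) training data
    should not hurt held-out micro-F1 relative to half the raw data.
    Evaluation and test splits are never augmented.
    """
    corpus = generate_corpus(GeneratorSpec(n_sentences=n_sentences, seed=seed))
    train, dev, test = split_corpus(corpus, (0.6, 0.2, 0.2), seed=seed)
    test_tokens = [s.tokens for s in test]
    results = []
    for i in range(n_seeds):
        run_seed = seed + 200 + i
        acfg = AugmentationConfig(
            daga_sample_count=2 * len(train), mr_pass_count=2, lm_epochs=15, seed=run_seed
        )
        hybrid, _, _ = hybrid_augment(train, acfg)
        rng = np.random.default_rng(run_seed)
        half_idx = sorted(rng.choice(len(train), size=len(train) // 2, replace=False))
        half = Corpus([train.sentences[j] for j in half_idx])
        cfg = EncoderConfig(**STUDENT_SHAPE)
        tc = TrainConfig(epochs=epochs, seed=run_seed)
        m_hybrid, _ = train_tagger(hybrid, dev, cfg, tc)
        f1_hybrid = evaluate(test, predict(m_hybrid, test_tokens)).micro.f1
        m_half, _ = train_tagger(half, dev, cfg, tc)
        f1_half = evaluate(test, predict(m_half, test_tokens)).micro.f1
        results.append((f1_hybrid, f1_half))
    return BenefitResult(results)


def metric_arithmetic_check() -> dict[str, float]:
    """The fixed-count fixture: TP=9, FP=1, FN=3."""
    from .evaluation import MatchCounts, score

    m = score({"PER": MatchCounts(tp=9, fp=1, fn=3)}).micro
    return {"precision": m.precision, "recall": m.recall, "f1": m.f1}
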