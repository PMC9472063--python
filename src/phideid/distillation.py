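"""Transformer-layer knowledge distillation: M-layer teacher to N-layer student.

The student learns three things from a frozen teacher, on the same input
stream:

* ``L_tr``  — for each mapped layer pair (student layer n, teacher layer
  k*n with M = k*N), the mean-squared error between attention maps
  (averaged over the h heads) plus the MSE between the student hidden
  state projected by ``W_h`` and the teacher hidden state;
* ``L_emb`` — MSE between the student embedding-layer output ``E^S`` and the
  teacher's, projected onto the student width: MSE(E^S, E^T W_e);
* ``L_pr``  — cross-entropy of the student's per-position label logits
  against the teacher's softmax distribution.

The total loss is their plain sum, ``L_total = L_tr + L_emb + L_pr``.  When
student and teacher share a width the projections may be the identity;
with identical states the first two losses are exactly 0 and ``L_pr`` sits
at its analytic floor, the teacher-distribution entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, parameter
from .corpus import Corpus
from .encoder import EncoderConfig, FeatureSequence, TransformerEncoder, tokenize


@dataclass(frozen=True)
class LayerMapping:
    """Student-to-teacher layer pairs (1-based), plus the embedding pair (0,0)."""

    k: int
    pairs: tuple[tuple[int, int], ...]


def map_layers(n_student: int, m_teacher: int) -> LayerMapping:
    """Uniform-stride mapping g: student layer n learns from teacher layer k*n."""
    if n_student < 1:
        raise ValueError("student must have at least 1 layer")
    if m_teacher % n_student:
        raise ValueError(
            f"teacher depth {m_teacher} not divisible by student depth {n_student}"
        )
    k = m_teacher // n_student
    pairs = tuple((n, k * n) for n in range(1, n_student + 1))
    return LayerMapping(k, ((0, 0),) + pairs)


@dataclass
class ProjectionParams:
    """Width-matching linear maps (identity when widths already agree).

    ``w_h`` carries the student hidden state onto the teacher width
    (used as ``H^S W_h`` vs ``H^T``); ``w_e`` carries the teacher embedding
    output onto the student width (used as ``E^S`` vs ``E^T W_e``).
    """

    w_h: Tensor
    w_e: Tensor

    @classmethod
    def create(
        cls, student_dim: int, teacher_dim: int, seed: int = 0
    ) -> "ProjectionParams":
        if student_dim == teacher_dim:
            w_h = parameter(np.eye(student_dim))
            w_e = parameter(np.eye(student_dim))
        else:
            rng = np.random.default_rng(seed)
            w_h = parameter(rng.normal(0, 0.05, size=(student_dim, teacher_dim)))
            w_e = parameter(rng.normal(0, 0.05, size=(teacher_dim, student_dim)))
        return cls(w_h, w_e)

    def parameters(self) -> list[Tensor]:
        return [self.w_h, self.w_e]


@dataclass
class TeacherStudentStates:
    teacher: FeatureSequence
    student: FeatureSequence
    teacher_logits: Tensor
    student_logits: Tensor


@dataclass
class DistillLosses:
    l_tr: float
    l_emb: float
    l_pr: float

    @property
    def l_total(self) -> float:
        return self.l_tr + self.l_emb + self.l_pr


def _mse(a: Tensor, b: Tensor) -> Tensor:
    diff = a - b
    return (diff * diff).mean()


def transformer_loss(
    states: TeacherStudentStates, mapping: LayerMapping, projections: ProjectionParams
) -> Tensor:
    """Attention-map MSE (mean over heads) + projected hidden-state MSE,
    summed over the mapped transformer layers."""
    total: Tensor | None = None
    for n, m in mapping.pairs:
        if n == 0:  # embedding pair handled by embedding_loss
            continue
        a_s = states.student.attention_maps[n - 1]
        a_t = states.teacher.attention_maps[m - 1]
        if a_s.shape[1] != a_t.shape[1]:
            raise ValueError(
                f"attention head mismatch: student {a_s.shape[1]} vs teacher {a_t.shape[1]}"
            )
        h_s = states.student.hidden_states[n - 1]
        h_t = states.teacher.hidden_states[m - 1]
        term = _mse(a_s, a_t) + _mse(h_s @ projections.w_h, h_t)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("layer mapping contains no transformer pairs")
    return total


def embedding_loss(e_s: Tensor, e_t: Tensor, w_e: Tensor) -> Tensor:
    """MSE between the student embedding output and the projected teacher's."""
    projected = e_t @ w_e
    if projected.shape != e_s.shape:
        raise ValueError(
            f"projected embedding shape {projected.shape} != student {e_s.shape}"
        )
    return _mse(e_s, projected)


def prediction_loss(
    z_t: Tensor, z_s: Tensor, mask: np.ndarray | None = None, temperature: float = 1.0
) -> Tensor:
    """Cross-entropy of student logits against the teacher's soft distribution.

    Minimum over the student is the teacher-distribution entropy, reached at
    ``Z^S == Z^T``.  Averaged per position; ``mask`` restricts to real tokens.
    """
    if not (np.all(np.isfinite(z_t.data)) and np.all(np.isfinite(z_s.data))):
        raise ValueError("non-finite logits")
    if z_t.shape[-1] != z_s.shape[-1]:
        raise ValueError("label dimensions differ between teacher and student")
    p_t = (z_t * (1.0 / temperature)).softmax(axis=-1)
    log_p_s = (z_s * (1.0 / temperature)).log_softmax(axis=-1)
    ce = -(Tensor(p_t.data) * log_p_s).sum(axis=-1)  # teacher is frozen
    if mask is None:
        return ce.mean()
    m = np.asarray(mask, dtype=np.float64)
    return (ce * Tensor(m)).sum() / max(m.sum(), 1.0)


def distillation_losses(
    states: TeacherStudentStates,
    mapping: LayerMapping,
    projections: ProjectionParams,
    mask: np.ndarray | None = None,
) -> tuple[Tensor, DistillLosses]:
    """Differentiable total loss plus its logged components (eq: sum of three)."""
    l_tr = transformer_loss(states, mapping, projections)
    l_emb = embedding_loss(
        states.student.embeddings, states.teacher.embeddings, projections.w_e
    )
    l_pr = prediction_loss(states.teacher_logits, states.student_logits, mask)
    total = l_tr + l_emb + l_pr
    return total, DistillLosses(l_tr.item(), l_emb.item(), l_pr.item())


def teacher_entropy(z_t: Tensor | np.ndarray, mask: np.ndarray | None = None) -> float:
    """Analytic floor of the prediction loss: mean entropy of teacher softmax."""
    z = z_t.data if isinstance(z_t, Tensor) else np.asarray(z_t)
    z = z - z.max(axis=-1, keepdims=True)
    p = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    ent = -(p * np.log(np.clip(p, 1e-300, None))).sum(axis=-1)
    if mask is None:
        return float(ent.mean())
    m = np.asarray(mask, dtype=np.float64)
    return float((ent * m).sum() / max(m.sum(), 1.0))


def distill(
    teacher: TransformerEncoder,
    student_config: EncoderConfig,
    corpus: Corpus,
    token_vocab: list[str],
    n_labels: int,
    steps: int = 100,
    batch_size: int = 16,
    lr: float = 5e-3,
    seed: int = 0,
    length_one: bool = False,
) -> tuple[TransformerEncoder, list[DistillLosses]]:
    """Train a fresh student to mimic a frozen teacher on ``corpus`` sentences.

    Returns the student and the per-step loss trace.  ``length_one`` feeds
    single-token sequences (the distillation regime the original compact
    encoder was built with); the default uses full sentences.
    """
    if len(corpus) == 0:
        raise ValueError("cannot distill on an empty corpus")
    mapping = map_layers(student_config.n_layers, teacher.config.n_layers)
    student = TransformerEncoder(student_config, n_labels=n_labels)
    projections = ProjectionParams.create(
        student_config.hidden_dim, teacher.config.hidden_dim, seed=seed
    )
    params = student.parameters() + projections.parameters()
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed)
    sentences = [s.tokens for s in corpus]
    if length_one:
        sentences = [[tok] for s in sentences for tok in s]
    trace: list[DistillLosses] = []
    for _ in range(steps):
        idx = rng.choice(len(sentences), size=min(batch_size, len(sentences)), replace=False)
        batch = tokenize([sentences[i] for i in idx], token_vocab, teacher.config.max_len)
        t_states, t_logits = teacher.forward(batch)
        s_states, s_logits = student.forward(batch)
        states = TeacherStudentStates(
            teacher=_freeze(t_states),
            student=s_states,
            teacher_logits=t_logits.detach(),
            student_logits=s_logits,
        )
        total, logged = distillation_losses(
            states, mapping, projections, mask=batch.attention_mask
        )
        if not np.isfinite(total.item()):
            raise RuntimeError(
                f"distillation diverged at step {len(trace)}: {logged}"
            )
        opt.zero_grad()
        total.backward()
        opt.step()
        trace.append(logged)
    return student, trace


def _freeze(states: FeatureSequence) -> FeatureSequence:
    return FeatureSequence(
        states.embeddings.detach(),
        [h.detach() for h in states.hidden_states],
        [a.detach() for a in states.attention_maps],
    )


def trace_to_csv(trace: list[DistillLosses], stream) -> None:
    stream.write("step,l_tr,l_emb,l_pr,l_total\n")
    for i, row in enumerate(trace):
        stream.write(f"{i},{row.l_tr},{row.l_emb},{row.l_pr},{row.l_total}\n")
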