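"""Distillation losses: analytic floors, hand-computed values, training runs."""

import numpy as np
import pytest

from phideid.autodiff import Tensor, parameter
from phideid.distillation import (
    DistillLosses,
    ProjectionParams,
    TeacherStudentStates,
    distill,
    distillation_losses,
    embedding_loss,
    map_layers,
    prediction_loss,
    teacher_entropy,
    transformer_loss,
)
from phideid.encoder import EncoderConfig, TransformerEncoder, tokenize
from phideid.synthetic import GeneratorSpec, generate_corpus

RNG = np.random.default_rng(0)


class TestLayerMapping:
    def test_stride_mapping(self):
        m = map_layers(2, 6)
        assert m.k == 3
        assert m.pairs == ((0, 0), (1, 3), (2, 6))

    def test_identity_mapping(self):
        m = map_layers(3, 3)
        assert m.k == 1
        assert m.pairs == ((0, 0), (1, 1), (2, 2), (3, 3))

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            map_layers(4, 6)


def _states(n_student, m_teacher, b=2, h=2, length=3, d=4, k=5, rng=RNG):
    def feat(n_layers):
        from phideid.encoder import FeatureSequence

        return FeatureSequence(
            Tensor(rng.normal(size=(b, length, d))),
            [Tensor(rng.normal(size=(b, length, d))) for _ in range(n_layers)],
            [Tensor(_rand_attn(rng, b, h, length)) for _ in range(n_layers)],
        )

    return TeacherStudentStates(
        teacher=feat(m_teacher),
        student=feat(n_student),
        teacher_logits=Tensor(rng.normal(size=(b, length, k))),
        student_logits=Tensor(rng.normal(size=(b, length, k))),
    )


def _rand_attn(rng, b, h, length):
    a = rng.random((b, h, length, length))
    return a / a.sum(-1, keepdims=True)


def _identity_projections(d):
    return ProjectionParams(parameter(np.eye(d)), parameter(np.eye(d)))


class TestTransformerLoss:
    def test_zero_distance_fixture(self):
        states = _states(2, 2)
        states.student.hidden_states = states.teacher.hidden_states
        states.student.attention_maps = states.teacher.attention_maps
        loss = transformer_loss(states, map_layers(2, 2), _identity_projections(4))
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_perturbation_gives_mean_squared_delta(self):
        states = _states(1, 1)
        delta = 0.3
        states.student.attention_maps = list(states.teacher.attention_maps)
        states.student.hidden_states = [
            Tensor(states.teacher.hidden_states[0].data + delta)
        ]
        loss = transformer_loss(states, map_layers(1, 1), _identity_projections(4))
        assert loss.item() == pytest.approx(delta**2, rel=1e-9)

    def test_batch_order_invariance(self):
        states = _states(1, 2, b=3)
        loss = transformer_loss(states, map_layers(1, 2), _identity_projections(4))
        perm = [2, 0, 1]

        def permute(fs):
            fs.hidden_states = [Tensor(h.data[perm]) for h in fs.hidden_states]
            fs.attention_maps = [Tensor(a.data[perm]) for a in fs.attention_maps]

        permute(states.teacher)
        permute(states.student)
        loss2 = transformer_loss(states, map_layers(1, 2), _identity_projections(4))
        assert loss.item() == pytest.approx(loss2.item(), rel=1e-12)

    def test_head_mismatch_rejected(self):
        states = _states(1, 1, h=2)
        states.student.attention_maps = [Tensor(_rand_attn(RNG, 2, 4, 3))]
        with pytest.raises(ValueError, match="head"):
            transformer_loss(states, map_layers(1, 1), _identity_projections(4))


class TestEmbeddingLoss:
    def test_exact_projection_gives_zero(self):
        e_t = Tensor(RNG.normal(size=(2, 3, 4)))
        w = parameter(RNG.normal(size=(4, 4)))
        e_s = Tensor(e_t.data @ w.data)
        assert embedding_loss(e_s, e_t, w).item() == pytest.approx(0.0, abs=1e-12)

    def test_scalar_exact_projection(self):
        # e_S = 1, e_T = 3, w_e = 1/3 -> perfectly projected, loss 0
        e_s = Tensor(np.array([[[1.0]]]))
        e_t = Tensor(np.array([[[3.0]]]))
        w = parameter(np.array([[1.0 / 3.0]]))
        assert embedding_loss(e_s, e_t, w).item() == pytest.approx(0.0)

    def test_scalar_unit_gap_gives_one(self):
        e_s = Tensor(np.array([[[1.0]]]))
        e_t = Tensor(np.array([[[2.0]]]))
        w = parameter(np.array([[1.0]]))
        assert embedding_loss(e_s, e_t, w).item() == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            embedding_loss(
                Tensor(np.zeros((1, 2, 3))),
                Tensor(np.zeros((1, 2, 4))),
                parameter(np.zeros((4, 5))),
            )


class TestPredictionLoss:
    def test_floor_is_teacher_entropy(self):
        z = Tensor(RNG.normal(size=(2, 4, 5)))
        loss = prediction_loss(z, Tensor(z.data.copy()))
        assert loss.item() == pytest.approx(teacher_entropy(z), rel=1e-12)

    def test_hard_teacher_reduces_to_cross_entropy(self):
        # near-one-hot teacher: loss approaches -log p_student(argmax)
        z_t = Tensor(np.array([[[50.0, 0.0, 0.0]]]))
        z_s = Tensor(np.array([[[1.0, 0.5, -0.5]]]))
        loss = prediction_loss(z_t, z_s)
        logp = z_s.log_softmax(axis=-1).data[0, 0, 0]
        assert loss.item() == pytest.approx(-logp, rel=1e-6)

    def test_monotone_along_line_toward_teacher(self):
        z_t = Tensor(RNG.normal(size=(1, 3, 4)))
        uniform = np.zeros_like(z_t.data)
        losses = [
            prediction_loss(z_t, Tensor(uniform + alpha * (z_t.data - uniform))).item()
            for alpha in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_non_finite_logits_rejected(self):
        bad = np.array([[[np.inf, 0.0]]])
        with pytest.raises(ValueError):
            prediction_loss(Tensor(bad), Tensor(np.zeros((1, 1, 2))))


class TestLossComposition:
    def test_total_is_sum_of_components(self):
        states = _states(2, 4)
        total, logged = distillation_losses(
            states, map_layers(2, 4), _identity_projections(4)
        )
        assert total.item() == pytest.approx(logged.l_total, rel=1e-15)
        assert logged.l_total == logged.l_tr + logged.l_emb + logged.l_pr

    def test_component_floors(self):
        states = _states(2, 4)
        _, logged = distillation_losses(states, map_layers(2, 4), _identity_projections(4))
        assert logged.l_tr >= 0 and logged.l_emb >= 0
        assert logged.l_pr >= teacher_entropy(states.teacher_logits) - 1e-12


@pytest.fixture(scope="module")
def distill_setup():
    corpus = generate_corpus(GeneratorSpec(n_sentences=60, length_range=(5, 12), seed=8))
    vocab = corpus.token_vocab()
    teacher = TransformerEncoder(
        EncoderConfig(
            n_layers=4, hidden_dim=16, n_heads=2, ffn_dim=32, max_len=16,
            vocab_size=len(vocab), seed=1,
        ),
        n_labels=9,
    )
    return corpus, vocab, teacher


class TestDistillRuns:
    def test_loss_decreases(self, distill_setup):
        corpus, vocab, teacher = distill_setup
        scfg = EncoderConfig(
            n_layers=2, hidden_dim=16, n_heads=2, ffn_dim=32, max_len=16,
            vocab_size=len(vocab), seed=2,
        )
        _, trace = distill(teacher, scfg, corpus, vocab, n_labels=9, steps=40, seed=0)
        assert trace[-1].l_total < trace[0].l_total
        for row in trace:
            assert row.l_total == pytest.approx(row.l_tr + row.l_emb + row.l_pr)

    def test_same_seed_identical_traces(self, distill_setup):
        corpus, vocab, teacher = distill_setup
        scfg = EncoderConfig(
            n_layers=2, hidden_dim=16, n_heads=2, ffn_dim=32, max_len=16,
            vocab_size=len(vocab), seed=2,
        )
        t1 = distill(teacher, scfg, corpus, vocab, n_labels=9, steps=10, seed=4)[1]
        t2 = distill(teacher, scfg, corpus, vocab, n_labels=9, steps=10, seed=4)[1]
        assert [r.l_total for r in t1] == [r.l_total for r in t2]

    def test_self_distillation_floor(self, distill_setup):
        """A frozen exact copy of the teacher sits at the analytic floor."""
        corpus, vocab, teacher = distill_setup
        batch = tokenize([corpus[0].tokens], vocab, 16)
        t_states, t_logits = teacher.forward(batch)
        states = TeacherStudentStates(t_states, t_states, t_logits, t_logits)
        _, logged = distillation_losses(
            states, map_layers(4, 4), _identity_projections(16),
            mask=batch.attention_mask,
        )
        assert logged.l_tr == pytest.approx(0.0, abs=1e-12)
        assert logged.l_emb == pytest.approx(0.0, abs=1e-12)
        assert logged.l_pr == pytest.approx(
            teacher_entropy(t_logits, batch.attention_mask), rel=1e-9
        )
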