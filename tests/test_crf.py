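"""Linear-chain CRF against the exhaustive-enumeration oracle."""

import numpy as np
import pytest

from conftest import brute_force_crf
from phideid.autodiff import Tensor
from phideid.crf import (
    CrfHead,
    bio_constraint_mask,
    export_transitions,
    log_partition,
    nll,
    sequence_score,
    viterbi,
)

RNG = np.random.default_rng(7)


def random_instance(rng, max_len=5, max_k=4):
    length = int(rng.integers(1, max_len + 1))
    k = int(rng.integers(2, max_k + 1))
    return rng.normal(size=(length, k)), rng.normal(size=(k + 2, k + 2))


class TestSequenceScore:
    def test_single_step(self):
        em = np.array([[2.0, -1.0]])
        tr = np.zeros((4, 4))
        ps = sequence_score(em, tr, [0])
        assert ps.emission_score == 2.0
        assert ps.transition_score == 0.0
        assert ps.total == 2.0

    def test_all_zero_scores(self):
        em = np.zeros((3, 2))
        tr = np.zeros((4, 4))
        for tags in ([0, 0, 0], [1, 0, 1]):
            assert sequence_score(em, tr, tags).total == 0.0

    def test_matches_hand_summation(self):
        rng = np.random.default_rng(3)
        em, tr = rng.normal(size=(3, 2)), rng.normal(size=(4, 4))
        tags = [1, 0, 1]
        expected = (
            em[0, 1] + em[1, 0] + em[2, 1]
            + tr[2, 1] + tr[1, 0] + tr[0, 1] + tr[1, 3]
        )
        assert sequence_score(em, tr, tags).total == pytest.approx(expected)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="tag"):
            sequence_score(np.zeros((2, 2)), np.zeros((4, 4)), [0, 5])


class TestLogPartition:
    def test_closed_form_single_position(self):
        # two labels, no scores anywhere: logZ = log 2
        em = np.array([[0.0, 0.0]])
        tr = np.zeros((4, 4))
        assert log_partition(em, tr) == pytest.approx(np.log(2.0))

    def test_matches_enumeration(self):
        for _ in range(60):
            em, tr = random_instance(RNG)
            logz, *_ = brute_force_crf(em, tr)
            assert log_partition(em, tr) == pytest.approx(logz, abs=1e-6)

    def test_emission_shift_identity(self):
        # adding c to every emission at one position shifts logZ by exactly c
        em, tr = random_instance(RNG, max_len=4)
        base = log_partition(em, tr)
        shifted = em.copy()
        shifted[0] += 2.5
        assert log_partition(shifted, tr) == pytest.approx(base + 2.5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            log_partition(np.zeros((0, 2)), np.zeros((4, 4)))


class TestNll:
    def test_single_label_vocabulary_gives_zero(self):
        em = RNG.normal(size=(4, 1))
        tr = RNG.normal(size=(3, 3))
        assert nll(em, tr, [0, 0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_equals_enumerated_gold_share(self):
        em, tr = random_instance(RNG)
        _, _, _, scores = brute_force_crf(em, tr)
        k = em.shape[1]
        gold = list(RNG.integers(0, k, size=em.shape[0]))
        loss = nll(em, tr, gold)
        gold_score = sequence_score(em, tr, gold).total
        share = np.exp(gold_score) / np.exp(scores).sum()
        assert np.exp(-loss) == pytest.approx(share, rel=1e-9)
        assert loss >= 0

    def test_path_probabilities_sum_to_one(self):
        em, tr = random_instance(RNG)
        logz, _, _, scores = brute_force_crf(em, tr)
        assert np.exp(scores - logz).sum() == pytest.approx(1.0, abs=1e-9)


class TestViterbi:
    def test_single_position_argmax(self):
        em = np.array([[0.5, 2.0, -1.0]])
        tr = np.zeros((5, 5))
        path, score = viterbi(em, tr)
        assert path == [1] and score == pytest.approx(2.0)

    def test_matches_exhaustive_argmax(self):
        for _ in range(60):
            em, tr = random_instance(RNG)
            _, best_path, best_score, _ = brute_force_crf(em, tr)
            path, score = viterbi(em, tr)
            assert score == pytest.approx(best_score, abs=1e-9)
            assert path == best_path

    def test_tie_breaks_to_lowest_label(self):
        # fully degenerate instance: every path ties; lowest indices win
        path, _ = viterbi(np.zeros((3, 3)), np.zeros((5, 5)))
        assert path == [0, 0, 0]

    def test_score_is_path_score(self):
        em, tr = random_instance(RNG)
        path, score = viterbi(em, tr)
        assert score == pytest.approx(sequence_score(em, tr, path).total)


class TestBioMask:
    LABELS = ["O", "B-PER", "I-PER", "B-LOC", "I-LOC", "B-ORG", "I-ORG", "B-DAT", "I-DAT"]

    def test_rule_enumeration(self):
        """The allowed predecessor set of each I- label is exactly {B-same, I-same}."""
        mask = bio_constraint_mask(self.LABELS)
        k = len(self.LABELS)
        for j, lab in enumerate(self.LABELS):
            if not lab.startswith("I-"):
                continue
            preds = {self.LABELS[i] for i in range(k) if mask[i, j]}
            assert preds == {f"B-{lab[2:]}", lab}

    def test_start_transitions(self):
        mask = bio_constraint_mask(self.LABELS)
        start = len(self.LABELS)
        assert mask[start, self.LABELS.index("B-PER")]
        assert not mask[start, self.LABELS.index("I-PER")]
        assert mask[self.LABELS.index("O"), self.LABELS.index("O")]

    def test_non_bio_label_rejected(self):
        with pytest.raises(ValueError, match="non-BIO"):
            bio_constraint_mask(["O", "S-PER"])

    def test_masked_decode_never_violates(self):
        mask = bio_constraint_mask(self.LABELS)
        rng = np.random.default_rng(11)
        for _ in range(25):
            em = rng.normal(scale=3.0, size=(8, len(self.LABELS)))
            tr = rng.normal(size=(len(self.LABELS) + 2,) * 2)
            path, _ = viterbi(em, tr, mask)
            tags = [self.LABELS[i] for i in path]
            from phideid.corpus import validate_bio

            assert validate_bio(tags) == []


class TestCrfHead:
    def test_batched_nll_matches_per_sentence(self):
        labels = ["O", "B-PER", "I-PER"]
        head = CrfHead(labels, seed=0)
        rng = np.random.default_rng(5)
        lengths = np.array([3, 2])
        em = rng.normal(size=(2, 3, 3))
        tags = np.array([[0, 1, 2], [1, 2, 0]])
        batched = head.nll(Tensor(em), tags, lengths).item()
        singles = [
            nll(em[i, : lengths[i]], head.transitions.data, tags[i, : lengths[i]])
            for i in range(2)
        ]
        assert batched == pytest.approx(np.mean(singles), abs=1e-9)

    def test_export_roundtrip(self, tmp_path):
        import json

        head = CrfHead(["O", "B-DAT", "I-DAT"], seed=1)
        path = tmp_path / "t.json"
        with open(path, "w") as fh:
            export_transitions(head.label_vocab, head.transitions.data, head.mask, fh)
        payload = json.loads(path.read_text())
        assert payload["labels"][-2:] == ["<START>", "<END>"]
        assert np.allclose(payload["scores"], head.transitions.data)
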