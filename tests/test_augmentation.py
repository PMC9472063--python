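"""DAGA linearization/generation and mention replacement contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phideid.augmentation import (
    BOS,
    EOS,
    AugmentationConfig,
    Rejection,
    StreamLm,
    build_mention_pool,
    daga_augment,
    delinearize,
    hybrid_augment,
    linearize,
    mention_replace,
    train_lm,
)
from phideid.corpus import Corpus, LabeledSentence, validate_bio
from phideid.synthetic import GeneratorSpec, generate_corpus


class TestLinearize:
    def test_marker_precedes_entity_tokens(self):
        s = LabeledSentence(["t1", "t2", "t3"], ["B-PER", "I-PER", "O"])
        assert linearize(s) == ["B-PER", "t1", "I-PER", "t2", "t3"]

    def test_all_o_sentence_is_bare(self):
        s = LabeledSentence(["a", "b"], ["O", "O"])
        assert linearize(s) == ["a", "b"]

    def test_invalid_bio_rejected(self):
        with pytest.raises(ValueError):
            linearize(LabeledSentence(["a"], ["I-PER"]))

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_round_trip_identity(self, data):
        corpus = generate_corpus(
            GeneratorSpec(
                n_sentences=1,
                length_range=(4, 15),
                seed=data.draw(st.integers(0, 10_000)),
            )
        )
        s = corpus[0]
        back = delinearize(linearize(s))
        assert not isinstance(back, Rejection)
        assert back.tokens == s.tokens and back.tags == s.tags


class TestDelinearize:
    def test_reconstructs_tags(self):
        out = delinearize(["B-DAT", "t1", "I-DAT", "t2"])
        assert out.tags == ["B-DAT", "I-DAT"]
        assert out.tokens == ["t1", "t2"]

    def test_initial_continuation_marker_rejected(self):
        out = delinearize(["I-PER", "t1"])
        assert isinstance(out, Rejection) and out.reason == "invalid-bio"

    def test_dangling_marker_rejected(self):
        out = delinearize(["B-PER", "B-PER", "t1"])
        assert isinstance(out, Rejection) and out.reason == "dangling-marker"

    def test_trailing_marker_rejected(self):
        out = delinearize(["t1", "B-LOC"])
        assert isinstance(out, Rejection) and out.reason == "dangling-marker"

    def test_empty_stream_rejected(self):
        assert delinearize([]).reason == "empty"


@pytest.fixture(scope="module")
def small_corpus():
    return generate_corpus(GeneratorSpec(n_sentences=80, length_range=(5, 14), seed=21))


class TestStreamLm:
    def test_repeated_bigram_memorized(self):
        """On a corpus of one repeated sentence, continuation probability ~ 1."""
        corpus = Corpus([LabeledSentence(["aa", "bb"], ["O", "O"])] * 20)
        cfg = AugmentationConfig(lm_epochs=80, lm_hidden_dim=16, seed=0)
        lm = train_lm(corpus, cfg)
        p = lm.next_distribution([BOS, "aa"])
        assert p[lm.index["bb"]] > 0.95

    def test_next_distribution_normalized(self, small_corpus):
        cfg = AugmentationConfig(lm_epochs=2, seed=0)
        lm = train_lm(small_corpus[:20], cfg)
        for prefix in ([BOS], [BOS, lm.vocab[3]], [BOS, lm.vocab[4], lm.vocab[5]]):
            assert lm.next_distribution(prefix).sum() == pytest.approx(1.0, abs=1e-6)

    def test_fixed_seed_identical_parameters(self, small_corpus):
        cfg = AugmentationConfig(lm_epochs=2, seed=9)
        a = train_lm(small_corpus[:15], cfg)
        b = train_lm(small_corpus[:15], cfg)
        np.testing.assert_array_equal(a.emb.data, b.emb.data)
        np.testing.assert_array_equal(a.out_w.data, b.out_w.data)

    def test_tiny_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            StreamLm(["only"])

    def test_argmax_sampling_regenerates_training_sentence(self):
        corpus = Corpus([LabeledSentence(["aa", "bb", "cc"], ["O", "O", "O"])] * 20)
        cfg = AugmentationConfig(lm_epochs=120, lm_hidden_dim=16, seed=1)
        lm = train_lm(corpus, cfg)
        stream = lm.sample(np.random.default_rng(0), max_len=10, temperature=0.0)
        assert stream == ["aa", "bb", "cc"]


class TestDaga:
    def test_all_accepted_sentences_valid(self, small_corpus):
        cfg = AugmentationConfig(daga_sample_count=60, lm_epochs=10, seed=3)
        sentences, stats = daga_augment(small_corpus, cfg)
        assert stats.accepted == len(sentences)
        assert all(validate_bio(s.tags) == [] for s in sentences)
        assert all(s.source == "daga" for s in sentences)

    def test_same_seed_identical_output(self, small_corpus):
        cfg = AugmentationConfig(daga_sample_count=20, lm_epochs=5, seed=5)
        a, _ = daga_augment(small_corpus, cfg)
        b, _ = daga_augment(small_corpus, cfg)
        assert [(s.tokens, s.tags) for s in a] == [(s.tokens, s.tags) for s in b]

    def test_zero_count_is_noop(self, small_corpus):
        sentences, stats = daga_augment(
            small_corpus, AugmentationConfig(daga_sample_count=0, seed=0)
        )
        assert sentences == [] and stats.requested == 0


class TestMentionReplace:
    def test_p_zero_is_identity(self, small_corpus):
        cfg = AugmentationConfig(replacement_prob=0.0, seed=0)
        out = mention_replace(small_corpus, cfg)
        assert [(s.tokens, s.tags) for s in out] == [
            (s.tokens, s.tags) for s in small_corpus
        ]

    def test_p_one_replaces_every_replaceable_entity(self, small_corpus):
        cfg = AugmentationConfig(replacement_prob=1.0, seed=0)
        pool = build_mention_pool(small_corpus)
        out = mention_replace(small_corpus, cfg, pool=pool)
        for before, after in zip(small_corpus, out):
            for s_before, s_after in zip(before.entities, after.entities):
                assert s_before.category == s_after.category
                if len(pool[s_before.category]) > 1:
                    assert after.mention(s_after) != before.mention(s_before)

    def test_outputs_valid_bio(self, small_corpus):
        out = mention_replace(small_corpus, AugmentationConfig(seed=2))
        assert all(validate_bio(s.tags) == [] for s in out)

    def test_replacement_rate_in_binomial_band(self):
        """With p=0.5 over >=1000 decisions the replaced fraction lies in 3 sigma."""
        corpus = generate_corpus(
            GeneratorSpec(n_sentences=900, length_range=(8, 20), seed=77, sparse_fraction=0.0)
        )
        pool = build_mention_pool(corpus)
        out = mention_replace(corpus, AugmentationConfig(replacement_prob=0.5, seed=13), pool)
        decisions = replaced = 0
        for before, after in zip(corpus, out):
            for s_b, s_a in zip(before.entities, after.entities):
                if len(pool[s_b.category]) > 1:
                    decisions += 1
                    replaced += before.mention(s_b) != after.mention(s_a)
        assert decisions >= 1000
        rate = replaced / decisions
        band = 3 * np.sqrt(0.25 / decisions)
        assert abs(rate - 0.5) <= band


class TestHybrid:
    def test_identity_when_counts_zero(self, small_corpus):
        cfg = AugmentationConfig(daga_sample_count=0, mr_pass_count=0, seed=0)
        out, summary, _ = hybrid_augment(small_corpus, cfg)
        assert len(out) == len(small_corpus)

    def test_summary_rows_sum(self, small_corpus):
        cfg = AugmentationConfig(daga_sample_count=30, mr_pass_count=1, lm_epochs=8, seed=1)
        out, summary, _ = hybrid_augment(small_corpus, cfg)
        for row in summary.rows.values():
            assert row["total"] == row["original"] + row["daga"] + row["mr"]

    def test_hybrid_contains_original(self, small_corpus):
        cfg = AugmentationConfig(daga_sample_count=10, mr_pass_count=1, lm_epochs=5, seed=1)
        out, _, _ = hybrid_augment(small_corpus, cfg)
        originals = [s for s in out if s.source == "original"]
        assert [(s.tokens, s.tags) for s in originals] == [
            (s.tokens, s.tags) for s in small_corpus
        ]
        assert len(out) > len(small_corpus)
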