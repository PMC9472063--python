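import itertools

import numpy as np
import pytest

from phideid.corpus import Corpus, LabeledSentence
from phideid.encoder import EncoderConfig
from phideid.synthetic import GeneratorSpec, generate_corpus


@pytest.fixture(scope="session")
def toy_corpus() -> Corpus:
    """Small seeded synthetic corpus shared by training-ish tests."""
    return generate_corpus(GeneratorSpec(n_sentences=120, length_range=(6, 20), seed=42))


@pytest.fixture()
def tiny_encoder_config() -> EncoderConfig:
    return EncoderConfig(
        n_layers=1, hidden_dim=16, n_heads=2, ffn_dim=32, max_len=12, vocab_size=10, seed=0
    )


@pytest.fixture()
def hand_sentence() -> LabeledSentence:
    return LabeledSentence(
        tokens=["w1", "p1", "p2", "w2", "d1"],
        tags=["O", "B-PER", "I-PER", "O", "B-DAT"],
    )


def brute_force_crf(emissions: np.ndarray, transitions: np.ndarray):
    """Exhaustive enumeration oracle: (logZ, best_path, best_score, all path scores).

    Scores every one of the K^L label paths directly from the definition
    (emission sum + boundary/pairwise transition sum); independent of the
    forward/Viterbi recursions it is used to check.
    """
    length, k = emissions.shape
    start, end = k, k + 1
    paths = np.array(list(itertools.product(range(k), repeat=length)))
    emit = emissions[np.arange(length), paths].sum(axis=1)
    trans = transitions[start, paths[:, 0]] + transitions[paths[:, -1], end]
    for i in range(length - 1):
        trans = trans + transitions[paths[:, i], paths[:, i + 1]]
    scores = emit + trans
    m = scores.max()
    logz = m + np.log(np.exp(scores - m).sum())
    best = int(scores.argmax())  # first maximizer = lowest lexicographic path
    return float(logz), list(paths[best]), float(scores[best]), scores
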