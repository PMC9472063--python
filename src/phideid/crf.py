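"""Linear-chain conditional random field: scoring, exact inference, decoding.

A path through labels ``y_1..y_L`` is scored as the sum of an emission part
(one score per position/label from the encoder) and a transition part (one
score per ordered label pair, with explicit START and END boundary states):

    score(y | s) = sum_i x_{i, y_i}
                 + x_{START -> y_1} + sum_i x_{y_i -> y_{i+1}} + x_{y_L -> END}

Training minimizes the negative log-likelihood ``logZ - score(gold)`` where
``logZ`` is the log-partition over all K^L paths, computed exactly by the
forward recursion.  Decoding is Viterbi, optionally restricted to
BIO-consistent transitions so that sequences such as ``B-PER I-ORG`` or a
sentence-initial ``I-`` can never be produced.

Inference functions here are plain numpy; :class:`CrfHead` wraps a learnable
transition matrix for gradient training of the full tagger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np

from .autodiff import Tensor, parameter

#: additive penalty for disallowed transitions; large enough to exclude any
#: masked path from both decoding and (optionally) the partition function
#: while keeping all arithmetic finite.
MASK_PENALTY = -1e4


@dataclass(frozen=True)
class PathScore:
    emission_score: float
    transition_score: float

    @property
    def total(self) -> float:
        return self.emission_score + self.transition_score


def _check(emissions: np.ndarray, n_labels: int | None = None) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise ValueError(f"emissions must be a nonempty LxK matrix, got {emissions.shape}")
    if not np.all(np.isfinite(emissions)):
        raise ValueError("emissions contain non-finite entries")
    if n_labels is not None and emissions.shape[1] != n_labels:
        raise ValueError("emission width does not match label count")
    return emissions


def _check_transitions(transitions: np.ndarray, k: int) -> np.ndarray:
    transitions = np.asarray(transitions, dtype=np.float64)
    if transitions.shape != (k + 2, k + 2):
        raise ValueError(
            f"transitions must be ({k + 2},{k + 2}) including START/END, got {transitions.shape}"
        )
    return transitions


def start_index(k: int) -> int:
    return k


def end_index(k: int) -> int:
    return k + 1


def sequence_score(
    emissions: np.ndarray, transitions: np.ndarray, tags: Sequence[int]
) -> PathScore:
    """Score one label path as emission_score + transition_score."""
    emissions = _check(emissions)
    length, k = emissions.shape
    transitions = _check_transitions(transitions, k)
    tags = list(tags)
    if len(tags) != length:
        raise ValueError(f"{len(tags)} tags for {length} positions")
    if any(not 0 <= t < k for t in tags):
        raise ValueError(f"tag outside label set of size {k}: {tags}")
    emit = float(sum(emissions[i, t] for i, t in enumerate(tags)))
    trans = transitions[start_index(k), tags[0]]
    for a, b in zip(tags, tags[1:]):
        trans += transitions[a, b]
    trans += transitions[tags[-1], end_index(k)]
    return PathScore(emit, float(trans))


def log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all K^L paths of exp(sequence_score), by the forward recursion."""
    emissions = _check(emissions)
    length, k = emissions.shape
    transitions = _check_transitions(transitions, k)
    inner = transitions[:k, :k]
    alpha = transitions[start_index(k), :k] + emissions[0]
    for i in range(1, length):
        # alpha_j' = logsumexp_a(alpha_a + T[a, j]) + e_{i,j}
        scores = alpha[:, None] + inner
        m = scores.max(axis=0)
        alpha = m + np.log(np.exp(scores - m).sum(axis=0)) + emissions[i]
    alpha = alpha + transitions[:k, end_index(k)]
    m = alpha.max()
    return float(m + np.log(np.exp(alpha - m).sum()))


def nll(emissions: np.ndarray, transitions: np.ndarray, tags: Sequence[int]) -> float:
    """Negative log-likelihood of the gold path: logZ - score(gold) >= 0."""
    return log_partition(emissions, transitions) - sequence_score(
        emissions, transitions, tags
    ).total


def viterbi(
    emissions: np.ndarray,
    transitions: np.ndarray,
    constraint_mask: np.ndarray | None = None,
) -> tuple[list[int], float]:
    """Best-scoring label path and its score.

    ``constraint_mask`` is a boolean (K+2, K+2) matrix of allowed transitions;
    disallowed ones receive the :data:`MASK_PENALTY`.  Ties break toward the
    lowest label index.
    """
    emissions = _check(emissions)
    length, k = emissions.shape
    transitions = _check_transitions(transitions, k)
    if constraint_mask is not None:
        constraint_mask = np.asarray(constraint_mask, dtype=bool)
        if constraint_mask.shape != transitions.shape:
            raise ValueError("constraint mask shape mismatch")
        transitions = transitions + MASK_PENALTY * ~constraint_mask
    inner = transitions[:k, :k]
    delta = transitions[start_index(k), :k] + emissions[0]
    back: list[np.ndarray] = []
    for i in range(1, length):
        scores = delta[:, None] + inner
        # argmax returns the first (lowest-index) maximizer: the tie-break rule
        best_prev = scores.argmax(axis=0)
        back.append(best_prev)
        delta = scores[best_prev, np.arange(k)] + emissions[i]
    final = delta + transitions[:k, end_index(k)]
    if constraint_mask is not None and final.max() <= length * MASK_PENALTY / 2:
        raise ValueError("no feasible path under the constraint mask")
    last = int(final.argmax())
    path = [last]
    for best_prev in reversed(back):
        last = int(best_prev[last])
        path.append(last)
    path.reverse()
    return path, float(final.max())


def bio_constraint_mask(label_vocab: Sequence[str]) -> np.ndarray:
    """Boolean (K+2, K+2) matrix of BIO-legal transitions over ``label_vocab``.

    Forbidden: START->I-*, O->I-*, B-X->I-Y and I-X->I-Y for X != Y, any
    inbound edge to START, any outbound edge from END, END->anything,
    anything->START.
    """
    k = len(label_vocab)
    cats: list[str | None] = []
    kinds: list[str] = []
    for lab in label_vocab:
        if lab == "O":
            kinds.append("O")
            cats.append(None)
        elif len(lab) > 2 and lab[1] == "-" and lab[0] in "BI":
            kinds.append(lab[0])
            cats.append(lab[2:])
        else:
            raise ValueError(f"non-BIO label in vocabulary: {lab!r}")
    mask = np.ones((k + 2, k + 2), dtype=bool)
    start, end = start_index(k), end_index(k)
    mask[:, start] = False
    mask[end, :] = False
    mask[start, end] = False
    for j in range(k):
        if kinds[j] == "I":
            mask[start, j] = False
    for i in range(k):
        for j in range(k):
            if kinds[j] != "I":
                continue
            if kinds[i] == "O" or cats[i] != cats[j]:
                mask[i, j] = False
    return mask


def export_transitions(
    label_vocab: Sequence[str],
    transitions: np.ndarray,
    mask: np.ndarray | None,
    stream: TextIO,
) -> None:
    """Dump labels, scores and the constraint mask as JSON for inspection."""
    payload = {
        "labels": list(label_vocab) + ["<START>", "<END>"],
        "scores": np.asarray(transitions).tolist(),
        "mask": None if mask is None else np.asarray(mask, dtype=int).tolist(),
    }
    json.dump(payload, stream, indent=1)


class CrfHead:
    """Learnable transition matrix with batched differentiable NLL.

    ``constrain_training=True`` applies the BIO mask (as an additive penalty)
    during training as well; the default applies it only at decode time.
    """

    def __init__(
        self,
        label_vocab: Sequence[str],
        seed: int = 0,
        constrain_training: bool = False,
    ):
        self.label_vocab = list(label_vocab)
        k = len(self.label_vocab)
        rng = np.random.default_rng(seed)
        self.transitions = parameter(rng.normal(0.0, 0.1, size=(k + 2, k + 2)))
        self.mask = bio_constraint_mask(self.label_vocab)
        self.constrain_training = constrain_training

    @property
    def n_labels(self) -> int:
        return len(self.label_vocab)

    def parameters(self) -> list[Tensor]:
        return [self.transitions]

    def _train_transitions(self) -> Tensor:
        if self.constrain_training:
            return self.transitions + Tensor(MASK_PENALTY * ~self.mask)
        return self.transitions

    def nll(self, emissions: Tensor, tags: np.ndarray, lengths: np.ndarray) -> Tensor:
        """Mean per-sentence negative log-likelihood over a padded batch.

        ``emissions`` is (B, L, K); ``tags`` integer (B, L); ``lengths`` gives
        the true length of each sequence (padding beyond it is ignored).
        """
        b, max_len, k = emissions.shape
        if k != self.n_labels:
            raise ValueError("emission width does not match CRF label count")
        lengths = np.asarray(lengths)
        if np.any(lengths < 1) or np.any(lengths > max_len):
            raise ValueError("sequence lengths must lie in [1, max_len]")
        trans = self._train_transitions()
        start, end = start_index(k), end_index(k)
        inner = trans[:k, :k]

        # --- gold path score -------------------------------------------------
        emit_picked = emissions.gather_last(tags[:, :, None]).reshape(b, max_len)
        step_mask = (np.arange(max_len)[None, :] < lengths[:, None]).astype(float)
        gold_emit = (emit_picked * Tensor(step_mask)).sum(axis=1)

        first = trans[start][tags[:, 0]]
        pair_scores = inner[tags[:, :-1], tags[:, 1:]]  # (B, L-1)
        pair_mask = (np.arange(1, max_len)[None, :] < lengths[:, None]).astype(float)
        gold_trans = first + (pair_scores * Tensor(pair_mask)).sum(axis=1)
        last_tags = tags[np.arange(b), lengths - 1]
        gold_trans = gold_trans + trans[:, end][last_tags]
        gold = gold_emit + gold_trans

        # --- forward recursion (batched) -------------------------------------
        alpha = trans[start, :k].reshape(1, k) + emissions[:, 0, :]
        for t in range(1, max_len):
            active = (lengths > t).astype(float)[:, None]
            scores = alpha.reshape(b, k, 1) + inner.reshape(1, k, k)
            new_alpha = scores.logsumexp(axis=1) + emissions[:, t, :]
            alpha = new_alpha * Tensor(active) + alpha * Tensor(1.0 - active)
        final = alpha + trans[:k, end].reshape(1, k)
        logz = final.logsumexp(axis=1)

        return ((logz - gold).sum()) / b

    def decode(
        self, emissions: np.ndarray, lengths: np.ndarray, constrained: bool = True
    ) -> list[list[int]]:
        """Constrained Viterbi decode of a padded batch, one path per sentence."""
        mask = self.mask if constrained else None
        out = []
        for row, length in zip(np.asarray(emissions), np.asarray(lengths)):
            path, _ = viterbi(row[: int(length)], self.transitions.data, mask)
            out.append(path)
        return out
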