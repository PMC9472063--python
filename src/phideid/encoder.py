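"""Multi-layer self-attention encoder producing per-token features and
CRF emission scores.

The architecture follows the BERT family: summed word/position/token-type
embeddings with layer norm, then a stack of post-norm transformer blocks
(multi-head self-attention + feed-forward, both with residual connections).
The same class serves as the compact student (default shape: 6 layers,
768-dim, 12 heads — the TinyBERT shape) and as a deeper teacher; tests run
it at much smaller widths.  Every layer's attention maps and hidden states
are exposed, because layer-wise distillation trains a student against them.

No pretrained weights are used; parameters are randomly initialized from a
seed and trained at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, gelu, parameter
from .corpus import PAD, UNK


@dataclass
class EncoderConfig:
    n_layers: int = 6
    hidden_dim: int = 768
    n_heads: int = 12
    ffn_dim: int | None = None  # defaults to 4 * hidden_dim
    vocab_size: int = 0
    n_token_types: int = 2
    max_len: int = 128
    dropout: float = 0.0
    softmax_emissions: bool = False  # pass probabilities instead of logits
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.hidden_dim


@dataclass
class TokenizedBatch:
    """Fixed-length id sequences ready for the embedding layer."""

    token_ids: np.ndarray  # (B, max_len) int
    position_ids: np.ndarray
    type_ids: np.ndarray
    attention_mask: np.ndarray  # (B, max_len) 1 on real tokens, 0 on pad
    lengths: np.ndarray  # true (possibly truncated) lengths
    truncated: np.ndarray  # bool per sentence

    @property
    def batch_size(self) -> int:
        return self.token_ids.shape[0]


@dataclass
class FeatureSequence:
    """Per-layer internals of one encoder forward pass."""

    embeddings: Tensor  # E: (B, L, D) embedding-layer output
    hidden_states: list[Tensor]  # H_i per layer, each (B, L, D)
    attention_maps: list[Tensor]  # A_i per layer, each (B, h, L, L)

    @property
    def features(self) -> Tensor:
        """Final per-token features (last hidden state, or E when 0 layers)."""
        return self.hidden_states[-1] if self.hidden_states else self.embeddings


def tokenize(
    sentences: Sequence[Sequence[str]],
    token_vocab: Sequence[str],
    max_len: int,
) -> TokenizedBatch:
    """Map token sequences onto fixed-length id arrays.

    Unknown surface units map to UNK; sentences longer than ``max_len`` are
    truncated (recorded in ``truncated`` so gold tags can be cut to match).
    """
    index = {tok: i for i, tok in enumerate(token_vocab)}
    if PAD not in index or UNK not in index:
        raise ValueError("token vocabulary must contain PAD and UNK entries")
    pad_id, unk_id = index[PAD], index[UNK]
    n = len(sentences)
    if any(len(s) == 0 for s in sentences):
        raise ValueError("cannot tokenize an empty sentence")
    token_ids = np.full((n, max_len), pad_id, dtype=np.int64)
    mask = np.zeros((n, max_len), dtype=np.int64)
    lengths = np.zeros(n, dtype=np.int64)
    truncated = np.zeros(n, dtype=bool)
    for r, sent in enumerate(sentences):
        ids = [index.get(tok, unk_id) for tok in sent]
        if len(ids) > max_len:
            ids = ids[:max_len]
            truncated[r] = True
        token_ids[r, : len(ids)] = ids
        mask[r, : len(ids)] = 1
        lengths[r] = len(ids)
    position_ids = np.tile(np.arange(max_len), (n, 1))
    type_ids = np.zeros((n, max_len), dtype=np.int64)
    return TokenizedBatch(token_ids, position_ids, type_ids, mask, lengths, truncated)


def vocab_fingerprint(vocab: Sequence[str]) -> int:
    """Stable hash of a vocabulary, stored in checkpoints to refuse mismatched loads."""
    import zlib

    return zlib.crc32("\x00".join(vocab).encode("utf-8"))


class TransformerEncoder:
    """Trainable encoder; owns embeddings, transformer blocks and emission head."""

    def __init__(self, config: EncoderConfig, n_labels: int | None = None):
        if config.vocab_size < 2:
            raise ValueError("vocab_size must cover at least PAD and UNK")
        self.config = config
        self.training = False
        self._drop_rng = np.random.default_rng(config.seed + 7919)
        d, f = config.hidden_dim, config.ffn_dim
        rng = np.random.default_rng(config.seed)
        scale = 0.02

        def p(*shape):
            return parameter(rng.normal(0.0, scale, size=shape))

        self.word_emb = p(config.vocab_size, d)
        self.pos_emb = p(config.max_len, d)  # learned positions
        self.type_emb = p(config.n_token_types, d)
        self.emb_gamma = parameter(np.ones(d))
        self.emb_beta = parameter(np.zeros(d))
        self.blocks: list[dict[str, Tensor]] = []
        for _ in range(config.n_layers):
            blk = {
                "wq": p(d, d), "bq": parameter(np.zeros(d)),
                "wk": p(d, d), "bk": parameter(np.zeros(d)),
                "wv": p(d, d), "bv": parameter(np.zeros(d)),
                "wo": p(d, d), "bo": parameter(np.zeros(d)),
                "ln1_g": parameter(np.ones(d)), "ln1_b": parameter(np.zeros(d)),
                "w1": p(d, f), "b1": parameter(np.zeros(f)),
                "w2": p(f, d), "b2": parameter(np.zeros(d)),
                "ln2_g": parameter(np.ones(d)), "ln2_b": parameter(np.zeros(d)),
            }
            self.blocks.append(blk)
        self.emission_w: Tensor | None = None
        self.emission_b: Tensor | None = None
        self.n_labels: int | None = None
        if n_labels is not None:
            self.set_emission_head(n_labels, rng)

    def set_emission_head(self, n_labels: int, rng: np.random.Generator | None = None):
        if n_labels < 2:
            raise ValueError("emission head needs at least 2 labels")
        if rng is None:
            rng = np.random.default_rng(self.config.seed + 1)
        self.n_labels = n_labels
        self.emission_w = parameter(
            rng.normal(0.0, 0.02, size=(self.config.hidden_dim, n_labels))
        )
        self.emission_b = parameter(np.zeros(n_labels))

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = [self.word_emb, self.pos_emb, self.type_emb, self.emb_gamma, self.emb_beta]
        for blk in self.blocks:
            params.extend(blk.values())
        if self.emission_w is not None:
            params.extend([self.emission_w, self.emission_b])
        return params

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward passes ---------------------------------------------------------
    def embed(self, batch: TokenizedBatch) -> Tensor:
        """Sum of word, position and token-type embeddings, layer-normalized."""
        for ids, table in (
            (batch.token_ids, self.word_emb),
            (batch.position_ids, self.pos_emb),
            (batch.type_ids, self.type_emb),
        ):
            if ids.max() >= table.shape[0] or ids.min() < 0:
                raise ValueError("id outside embedding table range")
        summed = (
            self.word_emb[batch.token_ids]
            + self.pos_emb[batch.position_ids]
            + self.type_emb[batch.type_ids]
        )
        return summed.layer_norm(self.emb_gamma, self.emb_beta)

    def _attention(self, x: Tensor, mask: np.ndarray, blk) -> tuple[Tensor, Tensor]:
        b, length, d = x.shape
        h = self.config.n_heads
        dh = d // h

        def heads(t: Tensor) -> Tensor:
            return t.reshape(b, length, h, dh).transpose(0, 2, 1, 3)

        q = heads(x @ blk["wq"] + blk["bq"])
        k = heads(x @ blk["wk"] + blk["bk"])
        v = heads(x @ blk["wv"] + blk["bv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        # keys at padded positions are unreachable
        neg = (1.0 - mask[:, None, None, :]) * -1e9
        attn = (scores + Tensor(neg)).softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, length, d)
        out = self._dropout(ctx @ blk["wo"] + blk["bo"])
        return out, attn

    def _dropout(self, t: Tensor) -> Tensor:
        rate = self.config.dropout
        if not self.training or rate <= 0.0:
            return t
        keep = (self._drop_rng.random(t.shape) >= rate) / (1.0 - rate)
        return t * Tensor(keep)

    def encode(self, embeddings: Tensor, mask: np.ndarray) -> FeatureSequence:
        """Run the block stack; collect each layer's hidden state and attention."""
        if embeddings.shape[-1] != self.config.hidden_dim:
            raise ValueError("embedding width does not match encoder config")
        mask = np.asarray(mask, dtype=np.float64)
        x = embeddings
        hidden, attns = [], []
        for blk in self.blocks:
            a_out, attn = self._attention(x, mask, blk)
            x = (x + a_out).layer_norm(blk["ln1_g"], blk["ln1_b"])
            f_out = self._dropout(gelu(x @ blk["w1"] + blk["b1"]) @ blk["w2"] + blk["b2"])
            x = (x + f_out).layer_norm(blk["ln2_g"], blk["ln2_b"])
            hidden.append(x)
            attns.append(attn)
        return FeatureSequence(embeddings, hidden, attns)

    def emissions(self, features: Tensor) -> Tensor:
        """Project per-token features to one score per label (CRF emissions).

        Raw logits by default; ``softmax_emissions`` normalizes per position
        (exposed for comparison, though a CRF renormalizes globally anyway).
        """
        if self.emission_w is None:
            raise ValueError("emission head not configured (call set_emission_head)")
        logits = features @ self.emission_w + self.emission_b
        if self.config.softmax_emissions:
            return logits.softmax(axis=-1)
        return logits

    def forward(self, batch: TokenizedBatch) -> tuple[FeatureSequence, Tensor]:
        states = self.encode(self.embed(batch), batch.attention_mask)
        return states, self.emissions(states.features)

    # -- persistence ------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {
            "word_emb": self.word_emb.data,
            "pos_emb": self.pos_emb.data,
            "type_emb": self.type_emb.data,
            "emb_gamma": self.emb_gamma.data,
            "emb_beta": self.emb_beta.data,
        }
        for i, blk in enumerate(self.blocks):
            for name, t in blk.items():
                arrays[f"block{i}.{name}"] = t.data
        if self.emission_w is not None:
            arrays["emission_w"] = self.emission_w.data
            arrays["emission_b"] = self.emission_b.data
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        self.word_emb.data = np.array(arrays["word_emb"])
        self.pos_emb.data = np.array(arrays["pos_emb"])
        self.type_emb.data = np.array(arrays["type_emb"])
        self.emb_gamma.data = np.array(arrays["emb_gamma"])
        self.emb_beta.data = np.array(arrays["emb_beta"])
        for i, blk in enumerate(self.blocks):
            for name in blk:
                blk[name].data = np.array(arrays[f"block{i}.{name}"])
        if "emission_w" in arrays:
            if self.emission_w is None:
                self.set_emission_head(arrays["emission_w"].shape[1])
            self.emission_w.data = np.array(arrays["emission_w"])
            self.emission_b.data = np.array(arrays["emission_b"])
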