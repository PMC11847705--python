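"""Transformer alternative to the recurrent EHR encoder.

Instead of pre-trained code embeddings averaged per day, the raw code
stream is tokenized — a sequence-start token, then each day's codes wrapped
in day-start / day-end markers, within-day order shuffled — and embedded
end-to-end. Token embeddings are scaled by sqrt(d), summed with sinusoidal
positional encodings, and passed through a stack of post-norm encoder
layers with multihead self-attention; padded key positions receive a large
negative additive attention score. The hidden state at the last non-padding
position is the latent patient representation, used exactly like the
recurrent latent state downstream (same freeze-and-transfer protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import PatientRecord
from .nn import Module, Embedding, TransformerEncoderLayer, Tensor

__all__ = [
    "PAD", "START", "DAY_START", "DAY_END", "N_SPECIAL",
    "TokenVocab", "TokenSequence", "TransformerConfig",
    "tokenize", "batch_tokens", "positional_encoding", "TransformerEncoderNet",
]

PAD, START, DAY_START, DAY_END = 0, 1, 2, 3
N_SPECIAL = 4
MAX_LEN = 1024


@dataclass
class TokenVocab:
    codes: list[str]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {c: i + N_SPECIAL for i, c in enumerate(self.codes)}

    @property
    def size(self) -> int:
        return len(self.codes) + N_SPECIAL

    @classmethod
    def from_records(cls, records: list[PatientRecord]) -> "TokenVocab":
        codes = sorted({c for r in records for _, cs in r.windowed_events
                        for c in cs})
        return cls(codes=codes)


@dataclass
class TokenSequence:
    tokens: list[int]  # <= MAX_LEN, starts with START

    @property
    def length(self) -> int:
        return len(self.tokens)


def tokenize(record: PatientRecord, vocab: TokenVocab,
             seed: int, max_len: int = MAX_LEN) -> TokenSequence:
    """Day-wrapped token stream; oldest tokens dropped beyond ``max_len``."""
    rng = np.random.default_rng(seed)
    body: list[int] = []
    for day, codes in sorted(record.windowed_events, key=lambda x: x[0]):
        known = [c for c in codes if c in vocab.index]
        if not known:
            continue
        order = rng.permutation(len(known))
        body.append(DAY_START)
        body.extend(vocab.index[known[i]] for i in order)
        body.append(DAY_END)
    if len(body) > max_len - 1:
        body = body[-(max_len - 1):]
    return TokenSequence(tokens=[START] + body)


def batch_tokens(seqs: list[TokenSequence], max_len: int = MAX_LEN
                 ) -> tuple[np.ndarray, np.ndarray]:
    """End-pad token sequences into (B, L) int ids with a (B, L) valid mask."""
    L = max(1, min(max_len, max(s.length for s in seqs)))
    ids = np.full((len(seqs), L), PAD, dtype=np.int64)
    mask = np.zeros((len(seqs), L), dtype=bool)
    for i, s in enumerate(seqs):
        t = s.tokens[:L]
        ids[i, :len(t)] = t
        mask[i, :len(t)] = True
    return ids, mask


@dataclass
class TransformerConfig:
    d: int = 128
    heads: int = 4
    layers: int = 2
    ff_dim: int = 512
    dropout: float = 0.1
    max_len: int = MAX_LEN

    def __post_init__(self):
        if self.d % 2 != 0:
            raise ValueError("model dimension must be even")
        if self.d % self.heads != 0:
            raise ValueError("heads must divide model dimension")


def positional_encoding(pos: int, cfg: TransformerConfig) -> np.ndarray:
    """PE(pos, 2i) = sin(pos / 10000^(2i/d)); PE(pos, 2i+1) = cos(...)."""
    if not 0 <= pos < cfg.max_len:
        raise ValueError("position outside the supported range")
    i = np.arange(cfg.d // 2)
    angle = pos / np.power(10000.0, 2 * i / cfg.d)
    pe = np.empty(cfg.d)
    pe[0::2] = np.sin(angle)
    pe[1::2] = np.cos(angle)
    return pe


def _pe_matrix(L: int, cfg: TransformerConfig) -> np.ndarray:
    return np.stack([positional_encoding(p, cfg) for p in range(L)])


class TransformerEncoderNet(Module):
    """Token embedding + positional encoding + masked encoder stack.

    Call signature matches the recurrent encoder: ``(ids, mask, rng,
    training) -> (B, d)`` latent, taken at the last non-padding position.
    """

    def __init__(self, vocab_size: int, cfg: TransformerConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.embedding = Embedding(vocab_size, cfg.d, rng)
        self.layers = [TransformerEncoderLayer(cfg.d, cfg.heads, cfg.ff_dim,
                                               cfg.dropout, rng)
                       for _ in range(cfg.layers)]
        self.hidden_dim = cfg.d

    def __call__(self, ids: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        B, L = ids.shape
        x = self.embedding(ids) * np.sqrt(self.cfg.d)
        x = x + Tensor(_pe_matrix(L, self.cfg)[None, :, :])
        for layer in self.layers:
            x = layer(x, mask, rng=rng, training=training)
        last = mask.sum(axis=1).astype(int) - 1
        last = np.maximum(last, 0)
        return x[np.arange(B), last, :]
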