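"""Day-grouped code "sentences", skip-gram embeddings, and daily summaries.

All concept codes recorded for one patient on one day form a sentence; the
within-day order is shuffled (sub-day timestamps in coded EHR data are
unreliable), and a skip-gram model with negative sampling learns one vector
per code from these sentences. A patient's encoder input is then the
chronological sequence of daily mean code embeddings, capped at the most
recent :data:`MAX_DAYS` days.

The skip-gram trainer is implemented here on numpy (mini-batched SGD over
(center, context) pairs with a unigram^0.75 negative-sampling table,
linearly decaying learning rate, single-threaded and deterministic for a
given seed).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_io import CohortBundle, PatientRecord

__all__ = [
    "MAX_DAYS", "DaySentence", "EmbeddingHyper", "CodeEmbeddingTable",
    "SummarySequence", "build_sentences", "train_embeddings", "summarize",
    "batch_sequences", "tables_for_bundle",
]

MAX_DAYS = 32  # encoder consumes at most this many most-recent days


@dataclass
class DaySentence:
    patient_id: str
    day_index: int
    codes: list[str]


@dataclass
class EmbeddingHyper:
    window: int = 5
    negative: int = 5
    min_count: int = 1
    epochs: int = 5
    lr: float = 0.025
    lr_min: float = 1e-4
    batch: int = 1024
    seed: int = 0


@dataclass
class CodeEmbeddingTable:
    codes: list[str]
    matrix: np.ndarray  # (V, d)
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {c: i for i, c in enumerate(self.codes)}

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, code: str) -> bool:
        return code in self.index

    def vector(self, code: str) -> np.ndarray:
        return self.matrix[self.index[code]]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for code, row in zip(self.codes, self.matrix):
                fh.write(code + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "CodeEmbeddingTable":
        codes, rows = [], []
        for line in Path(path).read_text().splitlines():
            parts = line.split("\t")
            codes.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        return cls(codes=codes, matrix=np.asarray(rows))


@dataclass
class SummarySequence:
    """Chronological daily mean embeddings (oldest first), at most MAX_DAYS
    rows; empty records yield a 0-row matrix."""

    matrix: np.ndarray       # (L, d)
    day_indices: list[int]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def build_sentences(records: list[PatientRecord], seed: int) -> list[DaySentence]:
    """One shuffled sentence per (patient, day) with at least one code."""
    rng = np.random.default_rng(seed)
    out: list[DaySentence] = []
    for rec in records:
        for day, codes in rec.windowed_events:
            if not codes:
                continue
            order = rng.permutation(len(codes))
            out.append(DaySentence(patient_id=rec.patient_id, day_index=day,
                                   codes=[codes[i] for i in order]))
    return out


def _neg_table(counts: np.ndarray, size: int = 1 << 17) -> np.ndarray:
    p = counts.astype(float) ** 0.75
    p /= p.sum()
    return np.searchsorted(np.cumsum(p), (np.arange(size) + 0.5) / size)


def train_embeddings(sentences: list[DaySentence], d: int,
                     hyper: EmbeddingHyper | None = None) -> CodeEmbeddingTable:
    """Skip-gram with negative sampling over the day sentences."""
    hyper = hyper or EmbeddingHyper()
    if not sentences:
        raise ValueError("cannot train embeddings on an empty corpus")
    counts = Counter(c for s in sentences for c in s.codes)
    vocab = sorted(c for c, n in counts.items() if n >= hyper.min_count)
    if not vocab:
        raise ValueError("no code meets min_count")
    index = {c: i for i, c in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(hyper.seed)

    # (center, context) pairs within the window, over encoded sentences
    centers, contexts = [], []
    for s in sentences:
        ids = [index[c] for c in s.codes if c in index]
        for i, ci in enumerate(ids):
            lo = max(0, i - hyper.window)
            hi = min(len(ids), i + hyper.window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(ci)
                    contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)

    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))
    if centers.size == 0:  # single-code sentences only: vectors stay at init
        return CodeEmbeddingTable(codes=vocab, matrix=W_in)

    freq = np.array([counts[c] for c in vocab])
    table = _neg_table(freq)
    n_pairs = centers.size
    total_steps = hyper.epochs * n_pairs

    step = 0
    for _ in range(hyper.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, hyper.batch):
            sel = order[start:start + hyper.batch]
            B = sel.size
            lr = max(hyper.lr_min,
                     hyper.lr * (1.0 - step / total_steps))
            c = centers[sel]
            pos = contexts[sel]
            neg = table[rng.integers(0, table.size, size=(B, hyper.negative))]
            vin = W_in[c]                      # (B, d)
            targets = np.concatenate([pos[:, None], neg], axis=1)  # (B, 1+neg)
            vout = W_out[targets]              # (B, 1+neg, d)
            score = np.einsum("bd,bkd->bk", vin, vout)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            gscore = (label - sig)             # (B, 1+neg)
            gin = np.einsum("bk,bkd->bd", gscore, vout)
            gout = gscore[:, :, None] * vin[:, None, :]
            np.add.at(W_in, c, lr * gin)
            np.add.at(W_out, targets.ravel(),
                      lr * gout.reshape(-1, gout.shape[-1]))
            step += B
    return CodeEmbeddingTable(codes=vocab, matrix=W_in)


def summarize(record: PatientRecord, table: CodeEmbeddingTable) -> SummarySequence:
    """Daily mean code embeddings for one record, most recent MAX_DAYS days.

    Codes outside the vocabulary are skipped; days with no embeddable codes
    are dropped and do not count toward the cap.
    """
    rows, days = [], []
    for day, codes in sorted(record.windowed_events, key=lambda x: x[0]):
        vecs = [table.vector(c) for c in codes if c in table]
        if vecs:
            rows.append(np.mean(vecs, axis=0))
            days.append(day)
    if len(rows) > MAX_DAYS:
        rows = rows[-MAX_DAYS:]
        days = days[-MAX_DAYS:]
    matrix = (np.asarray(rows) if rows
              else np.zeros((0, table.d)))
    return SummarySequence(matrix=matrix, day_indices=days)


def batch_sequences(seqs: list[SummarySequence], d: int,
                    max_len: int = MAX_DAYS) -> tuple[np.ndarray, np.ndarray]:
    """Front-pad summary sequences into (B, L, d) with a (B, L) valid mask."""
    L = max(1, min(max_len, max((s.length for s in seqs), default=1)))
    X = np.zeros((len(seqs), L, d))
    mask = np.zeros((len(seqs), L), dtype=bool)
    for i, s in enumerate(seqs):
        m = s.matrix[-L:]
        if m.shape[0]:
            X[i, L - m.shape[0]:] = m
            mask[i, L - m.shape[0]:] = True
    return X, mask


def tables_for_bundle(bundle: CohortBundle, d: int,
                      hyper: EmbeddingHyper | None = None,
                      shared: bool = False
                      ) -> tuple[CodeEmbeddingTable, CodeEmbeddingTable]:
    """Embedding tables for (pretraining, omics) cohorts.

    By default each cohort trains its own table; with ``shared=True`` a
    single table trained on the pretraining corpus serves both, keeping the
    two cohorts in one embedding space (required for meaningful frozen-
    weight transfer at small scale; see the methods note).
    """
    hyper = hyper or EmbeddingHyper()
    seed = hyper.seed
    pre_sent = build_sentences(bundle.pretraining, seed)
    pre_table = train_embeddings(pre_sent, d, hyper)
    if shared:
        return pre_table, pre_table
    om_sent = build_sentences(bundle.omics, seed + 1)
    om_hyper = EmbeddingHyper(**{**hyper.__dict__, "seed": seed + 1})
    om_table = train_embeddings(om_sent, d, om_hyper)
    return pre_table, om_table
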