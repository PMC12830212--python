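"""Distributed k-mer representations via CBOW.

Treats each transcript's k-mer token list as one sentence and trains a
continuous bag-of-words model: the averaged input vectors of the
context window predict the center k-mer through a softmax over the
vocabulary. Because the default vocabulary is tiny (64 possible
3-mers) the softmax is computed exactly — no negative sampling or
hierarchical approximation is needed — which also makes training fully
deterministic under a fixed seed. The learned input vectors serve as
node features for the attention network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .debruijn import KmerGraph
from .seqio import SKIP

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    """k-mer -> dense vector lookup with training provenance."""

    vocab: list[str]
    vectors: np.ndarray            # (|vocab|, d)
    k: int
    training_meta: dict = field(default_factory=dict)
    _index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.vocab)}
        assert np.all(np.isfinite(self.vectors))
        assert len(self.vocab) == self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._index

    def vector(self, kmer: str) -> np.ndarray:
        return self.vectors[self._index[kmer]]

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\td={self.d}\t{self.training_meta}\n")
            for w, v in zip(self.vocab, self.vectors):
                fh.write(w + "\t" + "\t".join(f"{x:.8g}" for x in v) + "\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "EmbeddingTable":
        vocab, rows = [], []
        meta: dict = {}
        k = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        if part.strip().startswith("k="):
                            k = int(part.strip()[2:])
                    continue
                fields = line.rstrip("\n").split("\t")
                vocab.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        if k is None:
            k = len(vocab[0])
        return cls(vocab, np.array(rows), k, meta)


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    d: int = 64,
    window: int = 5,
    epochs: int = 10,
    seed: int = 0,
    lr: float = 0.05,
    batch_size: int = 512,
) -> EmbeddingTable:
    """Train CBOW k-mer embeddings on tokenized sequences.

    Every k-mer appearing in the corpus enters the vocabulary (min
    count 1). Skip markers are removed from sentences before windowing.
    Identical corpus, parameters and seed reproduce an identical table.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if d < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {d}")
    sentences = [[t for t in sent if t != SKIP] for sent in corpus]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError("corpus contains no unambiguous k-mers")
    vocab = sorted({t for s in sentences for t in s})
    index = {w: i for i, w in enumerate(vocab)}
    k = len(vocab[0])
    V = len(vocab)
    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, d)) - 0.5) / d       # word2vec-style init
    w_out = np.zeros((d, V))

    # Precompute (center, padded-context) pairs for all positions.
    centers_all, ctx_all = [], []
    for s in sentences:
        ids = np.array([index[t] for t in s], dtype=np.int64)
        n = len(ids)
        for pos in range(n):
            lo, hi = max(0, pos - window), min(n, pos + window + 1)
            ctx = np.concatenate([ids[lo:pos], ids[pos + 1 : hi]])
            if ctx.size == 0:
                continue
            pad = np.full(2 * window, -1, dtype=np.int64)
            pad[: ctx.size] = ctx
            centers_all.append(ids[pos])
            ctx_all.append(pad)
    centers = np.array(centers_all, dtype=np.int64)
    contexts = np.stack(ctx_all)
    n_pos = len(centers)

    for _epoch in range(epochs):
        perm = rng.permutation(n_pos)
        for start in range(0, n_pos, batch_size):
            sel = perm[start : start + batch_size]
            c_ids = centers[sel]
            ctx = contexts[sel]                       # (B, 2*window), -1 padded
            mask = ctx >= 0
            counts = mask.sum(axis=1, keepdims=True)  # >=1 by construction
            vecs = w_in[np.where(mask, ctx, 0)] * mask[:, :, None]
            h = vecs.sum(axis=1) / counts             # (B, d) context mean
            logits = h @ w_out                        # (B, V)
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(len(sel)), c_ids] -= 1.0      # dsoftmax-CE
            # summed (not mean) batch gradient: approximates word2vec's
            # sequential per-position SGD updates at this learning rate
            grad_h = p @ w_out.T                      # (B, d)
            w_out -= lr * (h.T @ p)
            contrib = ((grad_h / counts)[:, None, :] * mask[:, :, None]).reshape(-1, d)
            ctx_flat = np.where(mask, ctx, V).reshape(-1)   # V = ignore slot
            onehot = ctx_flat[:, None] == np.arange(V)[None, :]
            w_in -= lr * (onehot.T.astype(float) @ contrib)

    meta = {"window": window, "epochs": epochs, "seed": seed, "lr": lr,
            "n_sentences": len(sentences), "n_positions": int(n_pos)}
    return EmbeddingTable(vocab, w_in, k, meta)


def embed_nodes(g: KmerGraph, table: EmbeddingTable) -> np.ndarray:
    """Node feature matrix (|nodes| x d), rows in graph node order.

    Out-of-vocabulary k-mers map to the zero vector with a warning;
    with the default k=3 every k-mer occurs in any realistic corpus,
    so this is an edge case rather than a modeling choice.
    """
    if g.k != table.k:
        raise ValueError(f"k mismatch: graph k={g.k}, embeddings k={table.k}")
    assert g.n_nodes > 0
    X = np.zeros((g.n_nodes, table.d))
    for m, km in enumerate(g.nodes):
        if km in table:
            X[m] = table.vector(km)
        else:
            logger.warning("k-mer %s absent from embedding vocabulary; zero vector used", km)
    return X
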