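"""Weighted De Bruijn graph construction over k-mers.

Each transcript becomes one directed graph: nodes are the distinct
k-mers observed in the sequence, and an edge i->j with raw weight
W_ij counts how often the (k+1)-mer spanning i and j occurs. Raw
counts are then degree-normalized,

    w_ij = W_ij / sqrt( S_down(i) * S_up(j) ),

with S_down(i) the sum of raw weights leaving i and S_up(j) the sum
of raw weights entering j. This symmetric-style normalization is
scale-invariant: doubling coverage leaves every normalized weight
unchanged, so the attention layer sees relative, not absolute, k-mer
adjacency structure. The literal product denominator (no square
root) is kept available as ``mode="product"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .seqio import SKIP


@dataclass
class KmerGraph:
    """Directed k-mer graph with raw and normalized edge weights."""

    sequence_id: str
    k: int
    nodes: list[str]                       # distinct k-mers, first-occurrence order
    edge_src: np.ndarray                   # int array, source node index per edge
    edge_dst: np.ndarray                   # int array, target node index per edge
    raw_weights: np.ndarray                # positive int per edge
    norm_weights: np.ndarray | None = None # set by normalize_edge_weights
    node_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {km: i for i, km in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    def edges(self) -> list[tuple[int, int]]:
        return list(zip(self.edge_src.tolist(), self.edge_dst.tolist()))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i, km in enumerate(self.nodes):
            g.add_node(i, kmer=km)
        for e in range(self.n_edges):
            attrs = {"raw_weight": int(self.raw_weights[e])}
            if self.norm_weights is not None:
                attrs["norm_weight"] = float(self.norm_weights[e])
            g.add_edge(int(self.edge_src[e]), int(self.edge_dst[e]), **attrs)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def build_graph(tokens: Sequence[str], k: int, sequence_id: str = "") -> KmerGraph:
    """Build the weighted De Bruijn graph from tokenized k-mers.

    Adjacent non-skip token pairs (t_m, t_{m+1}) contribute one count
    to the edge t_m -> t_{m+1}; no edge ever spans a skip marker.
    Self-loops from homopolymer runs are legitimate counts and kept.
    """
    node_index: dict[str, int] = {}
    nodes: list[str] = []
    edge_counts: dict[tuple[int, int], int] = {}
    for tok in tokens:
        if tok is not SKIP and tok != SKIP and tok not in node_index:
            node_index[tok] = len(nodes)
            nodes.append(tok)
    for a, b in zip(tokens, tokens[1:]):
        if a == SKIP or b == SKIP:
            continue
        key = (node_index[a], node_index[b])
        edge_counts[key] = edge_counts.get(key, 0) + 1
    if not edge_counts:
        raise ValueError(
            f"sequence {sequence_id!r} yields no edges "
            "(needs at least two consecutive unambiguous k-mers)"
        )
    # deterministic edge order: first occurrence along the sequence
    order: dict[tuple[int, int], int] = {}
    for a, b in zip(tokens, tokens[1:]):
        if a == SKIP or b == SKIP:
            continue
        key = (node_index[a], node_index[b])
        if key not in order:
            order[key] = len(order)
    edges = sorted(edge_counts, key=order.__getitem__)
    src = np.array([e[0] for e in edges], dtype=np.int64)
    dst = np.array([e[1] for e in edges], dtype=np.int64)
    w = np.array([edge_counts[e] for e in edges], dtype=np.int64)
    return KmerGraph(sequence_id, k, nodes, src, dst, w, node_index=node_index)


def normalize_edge_weights(g: KmerGraph, mode: str = "sqrt") -> KmerGraph:
    """Set ``norm_weights`` from raw counts (in place; graph returned).

    mode="sqrt": W_ij / sqrt(S_down(i) * S_up(j))  (default)
    mode="product": W_ij / (S_down(i) * S_up(j))
    """
    if mode not in ("sqrt", "product"):
        raise ValueError(f"unknown edge normalization mode {mode!r}")
    out_sum = np.zeros(g.n_nodes)
    in_sum = np.zeros(g.n_nodes)
    np.add.at(out_sum, g.edge_src, g.raw_weights.astype(float))
    np.add.at(in_sum, g.edge_dst, g.raw_weights.astype(float))
    denom = out_sum[g.edge_src] * in_sum[g.edge_dst]
    assert np.all(denom > 0), "edge with zero out/in weight sum: broken graph"
    if mode == "sqrt":
        denom = np.sqrt(denom)
    g.norm_weights = g.raw_weights / denom
    return g


def graph_from_sequence(seq, k: int, mode: str = "sqrt") -> KmerGraph:
    """Convenience: tokenize, build, and normalize in one call."""
    from .seqio import tokenize_kmers

    return normalize_edge_weights(build_graph(tokenize_kmers(seq, k), k, seq.id), mode)
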