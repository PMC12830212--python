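"""Interpretability analytics for trained attention ensembles.

The attention coefficients learned by the graph layer are treated as a
probability distribution per k-mer node, and several analyses read
biology out of them:

* attention entropy — Shannon entropy (bits) of each node's attention
  distribution over its neighborhood; high entropy means the k-mer
  integrates context broadly.
* entropy-frequency correlation — Spearman correlation between a
  k-mer's mean entropy and its mean occurrence frequency, per class.
* rank shift — k-mers ranked by mean entropy within each class; large
  rank shifts flag k-mers the model attends to differently in
  bifunctional vs non-bifunctional transcripts (start codons such as
  ATG shift toward the positive class).
* attention network + EPC centrality — a per-transcript k-mer
  interaction network weighted by ensemble-averaged attention, scored
  by edge-percolated-component centrality: a node's score is the
  expected size of its connected component when each edge is retained
  independently with probability equal to its weight.
* motif enrichment — presence/absence chi-squared test for a motif
  (e.g. the Kozak-like hexamer GCCATG) between classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import gatnet
from .debruijn import graph_from_sequence
from .embeddings import embed_nodes
from .gatnet import AttentionRecord
from .seqio import NucleotideSequence, tokenize_kmers
from .trainer import FoldEnsemble


@dataclass
class EntropyProfile:
    """Per-node attention entropy and k-mer frequency for one sequence."""

    sequence_id: str
    kmers: list[str]
    entropy: np.ndarray        # bits, per node
    frequency: np.ndarray      # occurrences of the k-mer in the sequence
    neighborhood_size: np.ndarray
    label: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sequence_id": self.sequence_id,
            "kmer": self.kmers,
            "frequency": self.frequency.astype(int),
            "entropy_bits": self.entropy,
        })


@dataclass
class AttentionNetwork:
    """k-mer interaction network of one transcript.

    Edge weight = attention coefficient averaged over heads (and
    ensemble members), renormalized per attending node so each node's
    incoming attention still sums to 1.
    """

    nodes: list[str]
    edge_src: np.ndarray
    edge_dst: np.ndarray
    weights: np.ndarray
    sequence_id: str = ""

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i, km in enumerate(self.nodes):
            g.add_node(i, kmer=km)
        for s, t, w in zip(self.edge_src, self.edge_dst, self.weights):
            g.add_edge(int(s), int(t), weight=float(w))
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def _aggregate_alpha(records: Sequence[AttentionRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean attention across heads and records, renormalized per node."""
    first = records[0]
    stacked = np.mean([r.alpha.mean(axis=0) for r in records], axis=0)
    denom = np.zeros(first.n_nodes)
    np.add.at(denom, first.att_dst, stacked)
    alpha = stacked / denom[first.att_dst]
    return first.att_src, first.att_dst, alpha, first.n_nodes


def attention_entropy(
    record: AttentionRecord | Sequence[AttentionRecord],
    kmer_counts: dict[str, int] | None = None,
    sequence_id: str = "",
    label: int | None = None,
) -> EntropyProfile:
    """Shannon entropy (bits) of each node's aggregated attention row.

    H_i = -sum_j alpha_ij log2 alpha_ij with 0 log 0 := 0. Attention is
    averaged over heads (and over ensemble members when several records
    are given) and renormalized before the entropy is taken.
    """
    records = [record] if isinstance(record, AttentionRecord) else list(record)
    src, dst, alpha, n = _aggregate_alpha(records)
    terms = np.where(alpha > 0, -alpha * np.log2(np.where(alpha > 0, alpha, 1.0)), 0.0)
    H = np.zeros(n)
    np.add.at(H, dst, terms)
    nbh = np.zeros(n, dtype=int)
    np.add.at(nbh, dst, 1)
    kmers = records[0].nodes or [str(i) for i in range(n)]
    if kmer_counts is not None:
        freq = np.array([kmer_counts.get(km, 0) for km in kmers], dtype=float)
    else:
        freq = np.ones(n)
    return EntropyProfile(sequence_id, list(kmers), H, freq, nbh, label)


def profile_sequences(
    seqs: Sequence[NucleotideSequence],
    ensemble: FoldEnsemble,
    labels: dict[str, int] | None = None,
) -> list[EntropyProfile]:
    """Entropy profiles for many sequences under a trained ensemble."""
    out = []
    cfg = ensemble.config
    for s in seqs:
        g = graph_from_sequence(s, cfg.k, cfg.edge_norm)
        X = embed_nodes(g, ensemble.embeddings)
        records = [gatnet.gat_forward(X, g, m)[1] for m in ensemble.members]
        tokens = [t for t in tokenize_kmers(s, cfg.k)]
        counts: dict[str, int] = {}
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
        out.append(attention_entropy(
            records, counts, s.id, labels.get(s.id) if labels else None
        ))
    return out


def _mean_by_kmer(profiles: Sequence[EntropyProfile]) -> pd.DataFrame:
    frames = [p.to_frame() for p in profiles]
    df = pd.concat(frames, ignore_index=True)
    return df.groupby("kmer").agg(
        mean_entropy=("entropy_bits", "mean"),
        mean_frequency=("frequency", "mean"),
    ).reset_index()


def entropy_frequency_correlation(
    profiles: Sequence[EntropyProfile],
) -> dict[int | None, tuple[float, float]]:
    """Spearman correlation of per-k-mer mean entropy vs mean frequency.

    Computed separately per class label; returns {label: (rho, p)}.
    Constant inputs yield (nan, nan) with a warning.
    """
    by_label: dict[int | None, list[EntropyProfile]] = {}
    for p in profiles:
        by_label.setdefault(p.label, []).append(p)
    out: dict[int | None, tuple[float, float]] = {}
    for label, group in by_label.items():
        agg = _mean_by_kmer(group)
        if len(agg) < 3:
            raise ValueError(f"need >= 3 k-mers per class, got {len(agg)}")
        if agg["mean_entropy"].nunique() == 1 or agg["mean_frequency"].nunique() == 1:
            warnings.warn(f"constant input for class {label}: correlation undefined")
            out[label] = (float("nan"), float("nan"))
            continue
        rho, pval = stats.spearmanr(agg["mean_frequency"], agg["mean_entropy"])
        out[label] = (float(rho), float(pval))
    return out


def _entropy_ranks(profiles: Sequence[EntropyProfile]) -> pd.Series:
    """Rank 1 = highest mean entropy; lexicographic tie-break on k-mer."""
    agg = _mean_by_kmer(profiles).sort_values(
        ["mean_entropy", "kmer"], ascending=[False, True]
    )
    return pd.Series(range(1, len(agg) + 1), index=agg["kmer"].to_list())


def rank_shift(
    pos_profiles: Sequence[EntropyProfile],
    neg_profiles: Sequence[EntropyProfile],
) -> pd.DataFrame:
    """Entropy-rank shift of each k-mer between classes.

    shift = rank_neg - rank_pos: positive shift means the k-mer has a
    relatively higher attention-entropy rank in the positive class.
    Sorted by |shift| descending.
    """
    if not pos_profiles or not neg_profiles:
        raise ValueError("both classes need at least one profile")
    rp = _entropy_ranks(pos_profiles)
    rn = _entropy_ranks(neg_profiles)
    common = sorted(set(rp.index) & set(rn.index))
    df = pd.DataFrame({
        "kmer": common,
        "rank_pos": [int(rp[k]) for k in common],
        "rank_neg": [int(rn[k]) for k in common],
    })
    df["shift"] = df["rank_neg"] - df["rank_pos"]
    return df.reindex(
        df["shift"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)


def build_attention_network(
    seq: NucleotideSequence, ensemble: FoldEnsemble
) -> AttentionNetwork:
    """Ensemble-averaged attention network for one transcript."""
    cfg = ensemble.config
    g = graph_from_sequence(seq, cfg.k, cfg.edge_norm)
    X = embed_nodes(g, ensemble.embeddings)
    records = [gatnet.gat_forward(X, g, m)[1] for m in ensemble.members]
    src, dst, alpha, _ = _aggregate_alpha(records)
    return AttentionNetwork(list(g.nodes), src, dst, alpha, seq.id)


def epc_centrality(
    net: AttentionNetwork, replicates: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Edge-percolated-component centrality of every k-mer node.

    Monte Carlo: in each replicate every edge is retained independently
    with probability equal to its weight (clamped to [0,1]); a node's
    score is the mean size of its weakly connected component across
    replicates. Returned sorted by score descending.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n = len(net.nodes)
    if n == 0:
        raise ValueError("empty attention network")
    # self-loops never change connectivity; drop them from percolation
    off = net.edge_src != net.edge_dst
    src, dst = net.edge_src[off], net.edge_dst[off]
    p_keep = np.clip(net.weights[off], 0.0, 1.0)
    rng = np.random.default_rng(seed)
    scores = np.zeros(n)
    for _ in range(replicates):
        keep = rng.random(p_keep.shape) < p_keep
        adj = coo_matrix(
            (np.ones(int(keep.sum())), (src[keep], dst[keep])), shape=(n, n)
        )
        _, comp = connected_components(adj, directed=True, connection="weak")
        sizes = np.bincount(comp, minlength=comp.max() + 1)
        scores += sizes[comp]
    scores /= replicates
    df = pd.DataFrame({"kmer": net.nodes, "epc_score": scores})
    return df.sort_values(
        ["epc_score", "kmer"], ascending=[False, True]
    ).reset_index(drop=True)


def motif_enrichment(
    pos_seqs: Sequence[NucleotideSequence],
    neg_seqs: Sequence[NucleotideSequence],
    motif: str = "GCCATG",
) -> tuple[float, float, np.ndarray]:
    """Presence/absence chi-squared test of a motif between classes.

    Contingency rows = class (positive, negative); columns = sequence
    contains >= 1 occurrence vs not. Pearson chi-squared, df = 1, no
    continuity correction (intended for hundreds of sequences).
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be non-empty over A/C/G/T, got {motif!r}")
    if not pos_seqs or not neg_seqs:
        raise ValueError("both classes need at least one sequence")
    pos_with = sum(motif in s.residues for s in pos_seqs)
    neg_with = sum(motif in s.residues for s in neg_seqs)
    table = np.array([
        [pos_with, len(pos_seqs) - pos_with],
        [neg_with, len(neg_seqs) - neg_with],
    ])
    if (table.sum(axis=0) == 0).any():
        raise ValueError(
            f"degenerate contingency table for motif {motif!r}: "
            "a presence/absence column is empty"
        )
    chi2, pval, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(chi2), float(pval), table
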