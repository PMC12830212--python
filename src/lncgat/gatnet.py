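"""Multi-head graph attention over k-mer De Bruijn graphs.

One attention layer with K concatenated heads, a mean readout, and a
two-layer fully connected head ending in a logistic output. For node i
with attention neighborhood N(i) (its in-neighbors, i.e. the k-mers
that precede it 5'->3', plus i itself), each head computes

    e_ij   = LeakyReLU( a^T [W h_i || W h_j] )
    alpha_ij = w_ij * exp(e_ij) / sum_m w_im * exp(e_im)
    h'_i   = alpha_ii W h_i + sum_{j in N(i)} alpha_ij W h_j

where w_ij is the normalized De Bruijn edge weight (w_ii = 1 for the
self term). Biasing the softmax multiplicatively by the edge weight is
how the graph's frequency structure enters the attention
distribution; ``edge_bias="none"`` disables it, leaving a plain GAT
softmax. Heads are concatenated, node outputs are mean-pooled into a
graph vector, and the FC stack maps it to P(bifunctional).

Everything is plain numpy. The backward pass is derived by hand and
verified against finite differences in the test suite; training with
Adam lives in :mod:`lncgat.trainer`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.special import expit

from .debruijn import KmerGraph

_LOG_EPS = 1e-300  # guard for log of tiny edge weights


@dataclass
class GatParameters:
    """All learnable tensors plus the fixed architectural hyperparameters."""

    weights: dict[str, np.ndarray]
    # weights keys:
    #   W  (K, hidden, d)   per-head node transform
    #   a1 (K, hidden)      attention vector, attending-node half
    #   a2 (K, hidden)      attention vector, neighbor half
    #   W1 (fc_hidden, K*hidden), b1 (fc_hidden,)
    #   w2 (fc_hidden,), b2 ()
    leaky_slope: float = 0.2
    dropout: float = 0.1
    edge_bias: str = "multiplicative"
    readout_mode: str = "mean"

    @property
    def heads(self) -> int:
        return self.weights["W"].shape[0]

    @property
    def hidden(self) -> int:
        return self.weights["W"].shape[1]

    @property
    def d(self) -> int:
        return self.weights["W"].shape[2]

    @property
    def fc_layers(self) -> list[int]:
        return [self.heads * self.hidden, self.weights["W1"].shape[0], 1]

    def copy(self) -> "GatParameters":
        return GatParameters(
            {k: v.copy() for k, v in self.weights.items()},
            self.leaky_slope, self.dropout, self.edge_bias, self.readout_mode,
        )

    def check_finite(self) -> None:
        for k, v in self.weights.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in parameter {k!r}")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.weights)
        manifest = {
            "shapes": {k: list(v.shape) for k, v in self.weights.items()},
            "heads": self.heads, "hidden": self.hidden, "d": self.d,
            "fc_layers": self.fc_layers, "leaky_slope": self.leaky_slope,
            "dropout": self.dropout, "edge_bias": self.edge_bias,
            "readout": self.readout_mode,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "GatParameters":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        with np.load(directory / "params.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        return cls(weights, manifest["leaky_slope"], manifest["dropout"],
                   manifest["edge_bias"], manifest.get("readout", "mean"))


@dataclass
class AttentionRecord:
    """Per-head attention coefficients over the attention edge list.

    The edge list is the graph's De Bruijn edges plus one self edge per
    node; ``alpha[k, e]`` is the coefficient head k assigns to message
    edge e (from att_src[e] into att_dst[e]). For every node and head
    the coefficients over incoming message edges sum to 1.
    """

    att_src: np.ndarray
    att_dst: np.ndarray
    alpha: np.ndarray            # (K, n_att_edges)
    n_nodes: int
    nodes: list[str] = field(default_factory=list)

    def row_sums(self) -> np.ndarray:
        """(K, n_nodes) sums of alpha per attending node — all ~1."""
        sums = np.zeros((self.alpha.shape[0], self.n_nodes))
        for k in range(self.alpha.shape[0]):
            np.add.at(sums[k], self.att_dst, self.alpha[k])
        return sums


def init_params(
    d: int = 64,
    hidden: int = 64,
    heads: int = 3,
    fc_hidden: int = 64,
    seed: int = 0,
    leaky_slope: float = 0.2,
    dropout: float = 0.1,
    edge_bias: str = "multiplicative",
    readout_mode: str = "mean",
) -> GatParameters:
    """Glorot-style initialization of all learnable tensors."""
    rng = np.random.default_rng(seed)

    def glorot(*shape):
        fan = sum(shape[-2:]) if len(shape) > 1 else shape[-1] + 1
        return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)

    weights = {
        "W": glorot(heads, hidden, d),
        "a1": glorot(heads, hidden) / np.sqrt(hidden),
        "a2": glorot(heads, hidden) / np.sqrt(hidden),
        "W1": glorot(fc_hidden, heads * hidden),
        "b1": np.zeros(fc_hidden),
        "w2": glorot(fc_hidden) / np.sqrt(fc_hidden),
        "b2": np.zeros(()),
    }
    return GatParameters(weights, leaky_slope, dropout, edge_bias, readout_mode)


def attention_edges(
    g: KmerGraph, edge_bias: str = "multiplicative"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Message edge list: De Bruijn edges plus self edges (weight 1).

    The attention formula carries exactly one self term per node, with
    weight 1; raw De Bruijn self-loops (homopolymer runs) are therefore
    not duplicated into the message list — they remain in the graph for
    frequency analytics but the self term supersedes them here.
    """
    if g.norm_weights is None:
        raise ValueError("graph edge weights not normalized; call normalize_edge_weights")
    n = g.n_nodes
    off = g.edge_src != g.edge_dst
    att_src = np.concatenate([g.edge_src[off], np.arange(n)])
    att_dst = np.concatenate([g.edge_dst[off], np.arange(n)])
    if edge_bias == "multiplicative":
        w = np.concatenate([g.norm_weights[off], np.ones(n)])
    elif edge_bias == "none":
        w = np.ones(att_src.shape[0])
    else:
        raise ValueError(f"unknown edge_bias {edge_bias!r}")
    return att_src, att_dst, w


def _segment_softmax(logit, seg, n_seg):
    """Numerically stable softmax of `logit` grouped by `seg`."""
    m = np.full(n_seg, -np.inf)
    np.maximum.at(m, seg, logit)
    ex = np.exp(logit - m[seg])
    denom = np.zeros(n_seg)
    np.add.at(denom, seg, ex)
    return ex / denom[seg]


def gat_forward(
    features: np.ndarray, g: KmerGraph, params: GatParameters
) -> tuple[np.ndarray, AttentionRecord]:
    """Run the attention layer on one graph.

    Returns the node output matrix (|nodes| x K*hidden) and the full
    attention record.
    """
    if features.shape[0] != g.n_nodes:
        raise ValueError(
            f"feature rows ({features.shape[0]}) != graph nodes ({g.n_nodes})"
        )
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite node features")
    params.check_finite()
    att_src, att_dst, w = attention_edges(g, params.edge_bias)
    n = g.n_nodes
    K, hidden = params.heads, params.hidden
    out = np.empty((n, K * hidden))
    alphas = np.empty((K, att_src.shape[0]))
    logw = np.log(np.maximum(w, _LOG_EPS))
    for k in range(K):
        H = features @ params.weights["W"][k].T
        sd = H @ params.weights["a1"][k]
        ss = H @ params.weights["a2"][k]
        pre = sd[att_dst] + ss[att_src]
        e = np.where(pre > 0, pre, params.leaky_slope * pre)
        alpha = _segment_softmax(e + logw, att_dst, n)
        agg = np.zeros((n, hidden))
        np.add.at(agg, att_dst, alpha[:, None] * H[att_src])
        out[:, k * hidden : (k + 1) * hidden] = agg
        alphas[k] = alpha
    record = AttentionRecord(att_src, att_dst, alphas, n, list(g.nodes))
    return out, record


def readout(node_outputs: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Pool node outputs into one graph-level vector."""
    if node_outputs.shape[0] == 0:
        raise ValueError("empty node output matrix")
    if mode == "mean":
        return node_outputs.mean(axis=0)
    if mode == "sum":
        return node_outputs.sum(axis=0)
    if mode == "max":
        return node_outputs.max(axis=0)
    raise ValueError(f"unknown readout mode {mode!r}")


def classify(graph_vector: np.ndarray, params: GatParameters) -> float:
    """FC stack (K*hidden -> fc_hidden -> 1) ending in a logistic output."""
    W1, b1 = params.weights["W1"], params.weights["b1"]
    if graph_vector.shape[0] != W1.shape[1]:
        raise ValueError(
            f"graph vector width {graph_vector.shape[0]} != FC input {W1.shape[1]}"
        )
    z1 = np.maximum(graph_vector @ W1.T + b1, 0.0)
    logit = z1 @ params.weights["w2"] + params.weights["b2"]
    return float(expit(logit))


def predict_proba(features: np.ndarray, g: KmerGraph, params: GatParameters) -> float:
    """Full single-graph forward: attention, readout, classification."""
    node_out, _ = gat_forward(features, g, params)
    return classify(readout(node_out, params.readout_mode), params)


# ---------------------------------------------------------------------------
# batched training path
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Several graphs packed into one disjoint union for vectorized passes.

    Message edges are stored sorted by destination node so that all
    per-node reductions run as contiguous ``np.add.reduceat`` segments;
    a second permutation sorted by source node serves the backward
    scatter. Every node owns a self edge, so both groupings cover all
    nodes and the segment boundaries are dense.
    """

    X: np.ndarray            # (N_total, d)
    att_src: np.ndarray      # dst-sorted
    att_dst: np.ndarray      # dst-sorted (non-decreasing)
    w: np.ndarray
    node_graph: np.ndarray   # graph index per node (non-decreasing)
    n_graphs: int
    labels: np.ndarray       # (n_graphs,) float 0/1
    dst_starts: np.ndarray   # segment starts per node in dst-sorted order
    graph_starts: np.ndarray # segment starts per graph over nodes
    S_dst: object            # csr (N x E): sums edge-indexed matrices by dst
    S_src: object            # csr (N x E): sums edge-indexed matrices by src


def make_batch(items: Sequence[tuple[np.ndarray, KmerGraph, int]],
               edge_bias: str = "multiplicative") -> GraphBatch:
    """Pack (features, graph, label) triples into one block-diagonal batch."""
    xs, srcs, dsts, ws, labels, sizes = [], [], [], [], [], []
    offset = 0
    for X, g, y in items:
        s, t, w = attention_edges(g, edge_bias)
        xs.append(X)
        srcs.append(s + offset)
        dsts.append(t + offset)
        ws.append(w)
        sizes.append(g.n_nodes)
        labels.append(y)
        offset += g.n_nodes
    src = np.concatenate(srcs)
    dst = np.concatenate(dsts)
    w = np.concatenate(ws)
    order = np.argsort(dst, kind="stable")
    src, dst, w = src[order], dst[order], w[order]
    n_nodes = offset
    n_edges = src.shape[0]
    dst_starts = np.searchsorted(dst, np.arange(n_nodes))
    node_graph = np.repeat(np.arange(len(items)), sizes)
    graph_starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    ones = np.ones(n_edges)
    cols = np.arange(n_edges)
    S_dst = sparse.csr_matrix((ones, cols, np.append(dst_starts, n_edges)),
                              shape=(n_nodes, n_edges))
    S_src = sparse.csr_matrix((ones, (src, cols)), shape=(n_nodes, n_edges))
    return GraphBatch(
        np.concatenate(xs), src, dst, w, node_graph, len(items),
        np.asarray(labels, dtype=float),
        dst_starts, graph_starts, S_dst, S_src,
    )


def batch_forward_backward(
    batch: GraphBatch,
    params: GatParameters,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """Mean binary cross-entropy over the batch, probabilities, gradients.

    Gradients are returned only when ``train=True`` (with inverted
    dropout on the FC input); in eval mode dropout is the identity and
    the gradient dict is None. Node features are fixed (the embedding
    table is not fine-tuned), so no gradient flows into X.
    """
    W = params.weights
    K, hidden = params.heads, params.hidden
    N = batch.X.shape[0]
    n_nodes_per_graph = np.bincount(batch.node_graph, minlength=batch.n_graphs).astype(float)
    slope = params.leaky_slope
    logwb = np.log(np.maximum(batch.w, _LOG_EPS))

    Hs, pres, alphas = [], [], []
    Hout = np.empty((N, K * hidden))
    for k in range(K):
        H = batch.X @ W["W"][k].T
        sd = H @ W["a1"][k]
        ss = H @ W["a2"][k]
        pre = sd[batch.att_dst] + ss[batch.att_src]
        e = np.where(pre > 0, pre, slope * pre)
        logit_a = e + logwb
        m = np.maximum.reduceat(logit_a, batch.dst_starts)
        ex = np.exp(logit_a - m[batch.att_dst])
        denom = np.add.reduceat(ex, batch.dst_starts)
        alpha = ex / denom[batch.att_dst]
        agg = batch.S_dst @ (alpha[:, None] * H[batch.att_src])
        Hout[:, k * hidden : (k + 1) * hidden] = agg
        Hs.append(H); pres.append(pre); alphas.append(alpha)

    # mean readout per graph
    G = np.add.reduceat(Hout, batch.graph_starts, axis=0)
    G /= n_nodes_per_graph[:, None]

    if train and params.dropout > 0:
        assert rng is not None, "training mode needs an RNG for dropout"
        mask = (rng.random(G.shape) >= params.dropout) / (1.0 - params.dropout)
        G_in = G * mask
    else:
        mask = None
        G_in = G

    pre1 = G_in @ W["W1"].T + W["b1"]
    z1 = np.maximum(pre1, 0.0)
    logit = z1 @ W["w2"] + W["b2"]
    p = expit(logit)
    eps = 1e-12
    y = batch.labels
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    if not train:
        return loss, p, None

    B = batch.n_graphs
    dlogit = (p - y) / B
    grads = {
        "b2": np.array(dlogit.sum()),
        "w2": z1.T @ dlogit,
    }
    dz1 = np.outer(dlogit, W["w2"])
    dpre1 = dz1 * (pre1 > 0)
    grads["W1"] = dpre1.T @ G_in
    grads["b1"] = dpre1.sum(axis=0)
    dG = dpre1 @ W["W1"]
    if mask is not None:
        dG = dG * mask
    dHout = dG[batch.node_graph] / n_nodes_per_graph[batch.node_graph, None]

    gW = np.empty_like(W["W"])
    ga1 = np.empty_like(W["a1"])
    ga2 = np.empty_like(W["a2"])
    for k in range(K):
        H, pre, alpha = Hs[k], pres[k], alphas[k]
        dout = dHout[:, k * hidden : (k + 1) * hidden]
        dalpha = np.einsum("eh,eh->e", dout[batch.att_dst], H[batch.att_src])
        msg = alpha[:, None] * dout[batch.att_dst]
        dH = batch.S_src @ msg
        # softmax backward within each attending node's edge group
        inner = np.add.reduceat(alpha * dalpha, batch.dst_starts)
        de = alpha * (dalpha - inner[batch.att_dst])
        dpre = de * np.where(pre > 0, 1.0, slope)
        gd = np.add.reduceat(dpre, batch.dst_starts)
        gs = np.bincount(batch.att_src, weights=dpre, minlength=N)
        ga1[k] = H.T @ gd
        ga2[k] = H.T @ gs
        dH += gd[:, None] * W["a1"][k] + gs[:, None] * W["a2"][k]
        gW[k] = dH.T @ batch.X
    grads["W"] = gW
    grads["a1"] = ga1
    grads["a2"] = ga2
    return loss, p, grads
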