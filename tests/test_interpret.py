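import itertools

import numpy as np
import pytest

from lncgat.gatnet import AttentionRecord
from lncgat.interpret import (
    AttentionNetwork,
    EntropyProfile,
    attention_entropy,
    entropy_frequency_correlation,
    epc_centrality,
    motif_enrichment,
    rank_shift,
)
from lncgat.seqio import NucleotideSequence


def record_from_rows(rows):
    """Build an AttentionRecord from explicit per-node alpha rows.

    rows[i] = dict {source_node: alpha}; one head.
    """
    src, dst, alpha = [], [], []
    for i, row in enumerate(rows):
        for j, a in row.items():
            src.append(j)
            dst.append(i)
            alpha.append(a)
    return AttentionRecord(
        np.array(src), np.array(dst), np.array([alpha]), len(rows),
        nodes=[f"n{i}" for i in range(len(rows))],
    )


class TestEntropy:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ({0: 1.0}, 0.0),
            ({0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25}, 2.0),
            ({0: 0.5, 1: 0.25, 2: 0.25}, 1.5),
        ],
    )
    def test_exact_values(self, row, expected):
        rec = record_from_rows([row] + [{0: 1.0}] * 3)
        profile = attention_entropy(rec)
        assert profile.entropy[0] == pytest.approx(expected)

    def test_zero_times_log_zero(self):
        rec = record_from_rows([{0: 1.0, 1: 0.0}, {0: 1.0}])
        assert attention_entropy(rec).entropy[0] == pytest.approx(0.0)

    def test_bounded_by_log_neighborhood(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            rows = []
            for i in range(n):
                members = rng.choice(n, size=int(rng.integers(1, n + 1)), replace=False)
                w = rng.random(len(members)) + 1e-3
                rows.append(dict(zip(members.tolist(), (w / w.sum()).tolist())))
            profile = attention_entropy(record_from_rows(rows))
            assert np.all(profile.entropy <= np.log2(profile.neighborhood_size) + 1e-9)
            assert np.all(profile.entropy >= 0)

    def test_multi_head_mean_renormalized(self):
        # two heads with different rows; aggregate = renormalized mean
        src = np.array([0, 1, 0, 1])
        dst = np.array([0, 0, 1, 1])
        alpha = np.array([[0.5, 0.5, 1.0, 0.0], [1.0, 0.0, 0.5, 0.5]])
        rec = AttentionRecord(src, dst, alpha, 2, nodes=["a", "b"])
        profile = attention_entropy(rec)
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert profile.entropy[0] == pytest.approx(expected)


def make_profile(sid, kmers, entropy, freq, label):
    return EntropyProfile(
        sid, kmers, np.asarray(entropy, dtype=float),
        np.asarray(freq, dtype=float), np.full(len(kmers), 4), label,
    )


class TestCorrelation:
    def test_monotone_and_antimonotone(self):
        kmers = [f"k{i}" for i in range(10)]
        up = [make_profile("a", kmers, range(10), range(10), 1)]
        down = [make_profile("b", kmers, range(10), range(10, 0, -1), 0)]
        res = entropy_frequency_correlation(up + down)
        assert res[1][0] == pytest.approx(1.0)
        assert res[0][0] == pytest.approx(-1.0)

    def test_random_pairs_near_zero(self, rng):
        kmers = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        ent = rng.permutation(64).astype(float)
        freq = rng.permutation(64).astype(float)
        res = entropy_frequency_correlation([make_profile("a", kmers, ent, freq, 1)])
        rho, p = res[1]
        assert abs(rho) < 0.35 and p > 1e-4

    def test_constant_input_warns_nan(self):
        prof = make_profile("a", ["k1", "k2", "k3"], [1, 1, 1], [1, 2, 3], 1)
        with pytest.warns(UserWarning, match="constant"):
            res = entropy_frequency_correlation([prof])
        assert np.isnan(res[1][0])


class TestRankShift:
    def test_identical_rankings_zero_shift(self):
        kmers = ["AAA", "CCC", "GGG"]
        pos = [make_profile("p", kmers, [3, 2, 1], [1, 1, 1], 1)]
        neg = [make_profile("n", kmers, [3, 2, 1], [1, 1, 1], 0)]
        df = rank_shift(pos, neg)
        assert (df["shift"] == 0).all()

    def test_reversed_rankings_max_shift(self):
        kmers = [f"k{i}" for i in range(6)]
        pos = [make_profile("p", kmers, range(6), [1] * 6, 1)]
        neg = [make_profile("n", kmers, range(6, 0, -1), [1] * 6, 0)]
        df = rank_shift(pos, neg)
        assert df["shift"].abs().max() == 5

    def test_hand_computed_shifts(self):
        # pos ranks (1,2,3) and neg ranks (3,1,2) -> shifts (+2,-1,-1)
        kmers = ["AAA", "CCC", "GGG"]
        pos = [make_profile("p", kmers, [9, 5, 3], [1] * 3, 1)]
        neg = [make_profile("n", kmers, [3, 9, 5], [1] * 3, 0)]
        df = rank_shift(pos, neg).set_index("kmer")
        assert df.loc["AAA", "shift"] == 2
        assert df.loc["CCC", "shift"] == -1
        assert df.loc["GGG", "shift"] == -1
        assert df.index[0] == "AAA"  # sorted by |shift| descending

    def test_empty_class_rejected(self):
        pos = [make_profile("p", ["AAA"], [1], [1], 1)]
        with pytest.raises(ValueError):
            rank_shift(pos, [])

    def test_lexicographic_tie_break(self):
        kmers = ["TTT", "AAA", "GGG"]
        pos = [make_profile("p", kmers, [1, 1, 1], [1] * 3, 1)]
        neg = [make_profile("n", kmers, [1, 1, 1], [1] * 3, 0)]
        df = rank_shift(pos, neg).set_index("kmer")
        # equal entropies: ranks assigned in k-mer order, shifts all 0
        assert df.loc["AAA", "rank_pos"] == 1
        assert (df["shift"] == 0).all()


def exhaustive_epc(net: AttentionNetwork) -> np.ndarray:
    """Exact expected component size by enumerating all edge subsets."""
    import networkx as nx

    off = net.edge_src != net.edge_dst
    edges = list(zip(net.edge_src[off], net.edge_dst[off]))
    probs = np.clip(net.weights[off], 0, 1)
    n = len(net.nodes)
    scores = np.zeros(n)
    for bits in itertools.product([0, 1], repeat=len(edges)):
        p_subset = np.prod([p if b else 1 - p for p, b in zip(probs, bits)])
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(e for e, b in zip(edges, bits) if b)
        for comp in nx.connected_components(g):
            for node in comp:
                scores[node] += p_subset * len(comp)
    return scores


class TestEpc:
    def test_full_weights_connected(self):
        # 5-node path, all weights 1 -> every score 5
        net = AttentionNetwork(
            [f"n{i}" for i in range(5)],
            np.arange(4), np.arange(1, 5), np.ones(4),
        )
        df = epc_centrality(net, replicates=10, seed=0)
        assert (df["epc_score"] == 5.0).all()

    def test_isolated_node(self):
        net = AttentionNetwork(["a", "b"], np.array([0]), np.array([0]), np.ones(1))
        df = epc_centrality(net, replicates=5, seed=0).set_index("kmer")
        assert df.loc["a", "epc_score"] == 1.0
        assert df.loc["b", "epc_score"] == 1.0

    def test_monte_carlo_matches_exhaustive(self, rng):
        """Estimator is unbiased on all enumerable networks (<= 6 edges)."""
        for trial in range(5):
            n = int(rng.integers(3, 6))
            n_edges = int(rng.integers(2, 7))
            src = rng.integers(0, n, n_edges)
            dst = rng.integers(0, n, n_edges)
            w = rng.random(n_edges)
            net = AttentionNetwork([f"n{i}" for i in range(n)], src, dst, w)
            exact = exhaustive_epc(net)
            R = 3000
            df = epc_centrality(net, replicates=R, seed=trial).set_index("kmer")
            got = np.array([df.loc[f"n{i}", "epc_score"] for i in range(n)])
            # 3 standard errors of a mean of component sizes bounded by n
            se = n / 2 / np.sqrt(R)
            assert np.all(np.abs(got - exact) <= 3 * se + 1e-9)

    def test_seeded_determinism(self, rng):
        net = AttentionNetwork(
            ["a", "b", "c"], np.array([0, 1]), np.array([1, 2]), np.array([0.5, 0.5])
        )
        a = epc_centrality(net, replicates=200, seed=9)
        b = epc_centrality(net, replicates=200, seed=9)
        assert a.equals(b)

    def test_empty_rejected(self):
        net = AttentionNetwork([], np.array([], int), np.array([], int), np.array([]))
        with pytest.raises(ValueError):
            epc_centrality(net, replicates=10, seed=0)


class TestMotif:
    def seqs(self, n, with_motif, rng, length=60):
        out = []
        for i in range(n):
            body = "".join(rng.choice(list("ACT"), length))  # no G: motif cannot arise
            if with_motif:
                body = body[:20] + "GCCATG" + body[26:]
            out.append(NucleotideSequence(f"s{with_motif}{i}", body))
        return out

    def test_equal_proportions_zero(self, rng):
        pos = self.seqs(10, True, rng) + self.seqs(10, False, rng)
        neg = self.seqs(10, True, rng) + self.seqs(10, False, rng)
        chi2, p, table = motif_enrichment(pos, neg, "GCCATG")
        assert chi2 == pytest.approx(0.0)

    def test_closed_form_value(self, rng):
        # contingency [[30,70],[5,95]]: chi2 = n(ad-bc)^2/(r1 r2 c1 c2) = 21.645
        pos = self.seqs(30, True, rng) + self.seqs(70, False, rng)
        neg = self.seqs(5, True, rng) + self.seqs(95, False, rng)
        chi2, p, table = motif_enrichment(pos, neg, "GCCATG")
        assert table.tolist() == [[30, 70], [5, 95]]
        expected = 200 * (30 * 95 - 70 * 5) ** 2 / (100 * 100 * 35 * 165)
        assert chi2 == pytest.approx(expected)
        assert chi2 == pytest.approx(21.645, abs=5e-4)
        assert p < 1e-5

    def test_absent_motif_degenerate(self, rng):
        pos = self.seqs(5, False, rng)
        neg = self.seqs(5, False, rng)
        with pytest.raises(ValueError, match="degenerate"):
            motif_enrichment(pos, neg, "GCCATG")

    def test_invalid_motif(self, rng):
        with pytest.raises(ValueError):
            motif_enrichment(self.seqs(2, True, rng), self.seqs(2, True, rng), "GCXATG")
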