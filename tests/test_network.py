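import numpy as np
import pandas as pd
import pytest

from awmnet.awm import Awm
from awmnet.network import (CoassocNetwork, first_order_partial,
                            gene_correlation_matrix, pcit_filter,
                            threshold_edges, topology)

from pcit_oracle import naive_pcit_edges, random_correlation


def net_from_edges(edges):
    nodes = sorted({a for a, b, _ in edges} | {b for a, b, _ in edges})
    return CoassocNetwork(nodes=nodes,
                          edges=pd.DataFrame(edges, columns=["node_a", "node_b", "r"]))


class TestCorrelation:
    def make_awm(self, X):
        v = pd.DataFrame(X, columns=[f"t{i}" for i in range(X.shape[1])])
        v.index = [f"g{i}" for i in range(len(v))]
        return Awm(values=v, provenance=pd.DataFrame({"feature_id": v.index}))

    def test_self_correlation_one_and_negation_minus_one(self, rng):
        x = rng.normal(size=12)
        R, _ = gene_correlation_matrix(self.make_awm(np.vstack([x, -x])))
        assert R.iloc[0, 0] == pytest.approx(1.0)
        assert R.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_pearson_oracle(self, rng):
        X = rng.normal(size=(30, 12))
        R, _ = gene_correlation_matrix(self.make_awm(X))
        for i in range(0, 30, 7):
            for j in range(0, 30, 5):
                a, b = X[i], X[j]
                am, bm = a - a.mean(), b - b.mean()
                r = (am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum())
                assert R.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_row_excluded_with_warning(self, rng):
        X = rng.normal(size=(4, 12))
        X[2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            R, dropped = gene_correlation_matrix(self.make_awm(X))
        assert dropped == ["g2"] and R.shape == (3, 3)


class TestPartial:
    def test_independent_conditioning_returns_direct(self):
        assert first_order_partial(0.6, 0.0, 0.0) == pytest.approx(0.6)

    def test_perfect_mediation_gives_zero(self):
        assert first_order_partial(0.35, 0.7, 0.5) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert first_order_partial(0.8, 0.5, 0.5) == pytest.approx((0.8 - 0.25) / 0.75)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            first_order_partial(0.5, 1.0, 0.5)


class TestPcit:
    def test_exact_zeros_yield_no_edges(self):
        net, _ = pcit_filter(np.eye(3))
        assert net.n_edges == 0

    def test_mediated_chain_edge_eliminated(self):
        """x-z-y chain with r_xy = r_xz * r_yz: the indirect edge goes."""
        r = 0.5
        R = np.array([[1.0, r * r, r],
                      [r * r, 1.0, r],
                      [r, r, 1.0]])
        net, decisions = pcit_filter(R, node_ids=["x", "y", "z"])
        pairs = set(map(tuple, net.edges[["node_a", "node_b"]].to_numpy()))
        assert ("x", "y") not in pairs
        assert ("x", "z") in pairs and ("y", "z") in pairs
        row = decisions.set_index(["node_a", "node_b"]).loc[("x", "y")]
        assert not row["kept"] and row["eliminating_node"] == "z"

    @pytest.mark.parametrize("block", [False, True])
    def test_matches_naive_oracle(self, rng, block):
        for _ in range(8):
            R = random_correlation(rng, 20, block=block)
            net, _ = pcit_filter(R)
            pos = {n: i for i, n in enumerate(net.nodes)}
            got = {(pos[a], pos[b]) for a, b in
                   net.edges[["node_a", "node_b"]].itertuples(index=False, name=None)}
            assert got == naive_pcit_edges(R)

    def test_never_adds_edges(self, rng):
        R = random_correlation(rng, 15)
        net, _ = pcit_filter(R)
        for a, b, r in net.edges.itertuples(index=False, name=None):
            assert R[net.nodes.index(a), net.nodes.index(b)] == pytest.approx(r)

    def test_node_relabeling_invariance(self, rng):
        R = random_correlation(rng, 12)
        perm = rng.permutation(12)
        net1, _ = pcit_filter(R, node_ids=[f"n{i}" for i in range(12)])
        net2, _ = pcit_filter(R[np.ix_(perm, perm)],
                              node_ids=[f"n{i}" for i in perm])
        e1 = {frozenset((a, b)) for a, b in
              net1.edges[["node_a", "node_b"]].itertuples(index=False, name=None)}
        e2 = {frozenset((a, b)) for a, b in
              net2.edges[["node_a", "node_b"]].itertuples(index=False, name=None)}
        assert e1 == e2

    def test_asymmetric_and_nan_rejected(self):
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError):
            pcit_filter(bad)
        nanny = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError):
            pcit_filter(nanny)

    def test_block_structure_recovery(self, rng):
        """Cross-module edge fraction < within-module after PCIT."""
        n = 30
        labels = np.repeat([0, 1], n // 2)
        base = rng.normal(size=(2, 12))
        X = base[labels] + rng.normal(0, 0.7, size=(n, 12))
        R = np.corrcoef(X)
        net, _ = pcit_filter(R)
        pos = {node: i for i, node in enumerate(net.nodes)}
        within = cross = 0
        for a, b in net.edges[["node_a", "node_b"]].itertuples(index=False, name=None):
            if labels[pos[a]] == labels[pos[b]]:
                within += 1
            else:
                cross += 1
        n_within_pairs = 2 * ((n // 2) * (n // 2 - 1) // 2)
        n_cross_pairs = (n // 2) ** 2
        assert cross / n_cross_pairs < within / n_within_pairs


class TestThreshold:
    def test_zero_threshold_is_identity(self):
        net = net_from_edges([("a", "b", 0.5), ("b", "c", -0.9)])
        out = threshold_edges(net, 0.0)
        assert out.n_edges == 2

    def test_exact_threshold_value_dropped(self):
        net = net_from_edges([("a", "b", 0.86), ("b", "c", 0.861)])
        out = threshold_edges(net, 0.86)
        assert out.n_edges == 1 and list(out.edges["node_a"]) == ["b"]
        assert out.nodes == ["b", "c"]  # "a" became isolated and is dropped

    def test_known_weights_hand_count(self):
        edges = [("a", "b", 0.9), ("a", "c", -0.95), ("c", "d", 0.3),
                 ("d", "e", -0.87), ("e", "f", 0.85)]
        out = threshold_edges(net_from_edges(edges), 0.86)
        assert out.n_edges == 3
        assert out.n_edges_pre_threshold == 5


class TestTopology:
    def test_three_node_path(self):
        net = net_from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        rep = topology(net)
        assert rep.mean_degree == pytest.approx(4 / 3)
        assert rep.mean_distance == pytest.approx(4 / 3)
        assert rep.n_unreachable_pairs == 0

    def test_star_degrees(self):
        net = net_from_edges([("hub", f"l{i}", 1.0) for i in range(6)])
        rep = topology(net)
        assert rep.degrees["hub"] == 6
        assert all(rep.degrees[f"l{i}"] == 1 for i in range(6))

    def test_mean_distance_matches_bfs_oracle(self, rng):
        n = 25
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.12:
                    edges.append((f"n{i:02d}", f"n{j:02d}", 1.0))
        net = net_from_edges(edges)
        rep = topology(net)

        # hand BFS over adjacency lists
        adj = {x: set() for x in net.nodes}
        for a, b, _ in edges:
            adj[a].add(b)
            adj[b].add(a)
        total = cnt = 0
        for s in net.nodes:
            dist = {s: 0}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            for t, d in dist.items():
                if d > 0:
                    total += d
                    cnt += 1
        assert rep.mean_distance == pytest.approx(total / cnt)
        assert rep.n_unreachable_pairs == len(net.nodes) * (len(net.nodes) - 1) - cnt
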