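"""Weighted efficiency, clustering and network-block FC against brute-force
and independent-library oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from planconn.graph_metrics import (
    CoherenceMatrix,
    NetworkPartition,
    RSN_NAMES,
    between_network_fc,
    clustering_coefficient,
    compute_topology_metrics,
    global_efficiency,
    metrics_table,
    subnetwork_metrics,
    within_network_fc,
)


def floyd_warshall_efficiency(w, edge_length="inverse"):
    """Brute-force all-pairs shortest paths on edge lengths 1/w."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j] if edge_length == "inverse" else -np.log(w[i, j])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))


def triple_enumeration_clustering(w):
    """Onnela weighted clustering by explicit enumeration of node triples."""
    n = w.shape[0]
    what = w / w.max() if w.max() > 0 else w
    per_node = np.zeros(n)
    for i in range(n):
        k_i = int((w[i] > 0).sum())
        if k_i < 2:
            continue
        total = 0.0
        for j, k in itertools.combinations(range(n), 2):
            if j == i or k == i:
                continue
            total += (what[i, j] * what[i, k] * what[j, k]) ** (1.0 / 3.0)
        per_node[i] = 2.0 * total / (k_i * (k_i - 1))
    return per_node, per_node.mean()


def random_weighted(rng, n, density=1.0):
    w = rng.uniform(0.05, 1.0, (n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        w = w * mask
    w = np.triu(w, 1)
    w = w + w.T
    return w


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        w = np.ones((5, 5))
        assert global_efficiency(w) == pytest.approx(1.0)

    def test_two_nodes_single_edge(self):
        for weight in (0.2, 0.7, 1.0):
            w = np.array([[0.0, weight], [weight, 0.0]])
            assert global_efficiency(w) == pytest.approx(weight)

    @pytest.mark.parametrize("edge_length", ["inverse", "neglog"])
    def test_matches_floyd_warshall_oracle(self, rng, edge_length):
        for trial in range(50):
            n = int(rng.integers(4, 13))
            w = random_weighted(rng, n, density=float(rng.uniform(0.4, 1.0)))
            got = global_efficiency(w, edge_length=edge_length)
            want = floyd_warshall_efficiency(w, edge_length=edge_length)
            assert got == pytest.approx(want, abs=1e-10)

    def test_monotone_in_single_weight_increase(self, rng):
        for _ in range(20):
            w = random_weighted(rng, 8)
            i, j = 1, 5
            w2 = w.copy()
            w2[i, j] = w2[j, i] = min(1.0, w[i, j] + 0.3)
            assert global_efficiency(w2) >= global_efficiency(w) - 1e-12

    def test_permutation_invariant(self, rng):
        w = random_weighted(rng, 9)
        perm = rng.permutation(9)
        assert global_efficiency(w[np.ix_(perm, perm)]) == pytest.approx(
            global_efficiency(w), abs=1e-12
        )

    def test_negative_weights_rejected(self):
        w = -np.ones((3, 3))
        with pytest.raises(ValueError, match="nonnegative"):
            global_efficiency(w)


class TestClustering:
    def test_unit_triangle(self):
        w = np.ones((3, 3))
        per_node, mean = clustering_coefficient(w)
        assert np.allclose(per_node, 1.0)
        assert mean == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        _, mean = clustering_coefficient(w)
        assert mean == 0.0

    def test_matches_triple_enumeration_oracle(self, rng):
        for trial in range(50):
            n = int(rng.integers(4, 13))
            w = random_weighted(rng, n, density=float(rng.uniform(0.4, 1.0)))
            per_node, mean = clustering_coefficient(w)
            want_nodes, want_mean = triple_enumeration_clustering(w)
            assert np.allclose(per_node, want_nodes, atol=1e-10)
            assert mean == pytest.approx(want_mean, abs=1e-10)

    def test_binary_graphs_match_networkx(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.5, seed=int(rng.integers(1e6)))
            w = nx.to_numpy_array(g)
            if w.sum() == 0:
                continue
            per_node, mean = clustering_coefficient(w)
            want = nx.clustering(g)
            got = dict(enumerate(per_node))
            for node in g:
                assert got[node] == pytest.approx(want[node], abs=1e-10)

    def test_too_few_nodes_flagged(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            clustering_coefficient(np.ones((2, 2)))


def _partitioned_matrix(rng, sizes):
    labels = {}
    i = 0
    for name, size in sizes.items():
        for _ in range(size):
            labels[f"n{i:02d}"] = name
            i += 1
    n = sum(sizes.values())
    w = random_weighted(rng, n)
    np.fill_diagonal(w, 1.0)
    return CoherenceMatrix(w, list(labels)), NetworkPartition(labels)


class TestSubnetworks:
    def test_clique_subnetwork_is_perfect(self):
        labels = {f"n{i}": "DMN" if i < 4 else "FPN" for i in range(8)}
        w = np.full((8, 8), 0.2)
        w[:4, :4] = 1.0
        np.fill_diagonal(w, 1.0)
        m = CoherenceMatrix(w, list(labels))
        part = NetworkPartition(labels)
        eff, cc = subnetwork_metrics(m, part, "DMN")
        assert eff == pytest.approx(1.0)
        assert cc == pytest.approx(1.0)

    def test_equals_global_ops_on_extracted_submatrix(self, rng):
        m, part = _partitioned_matrix(
            rng, {"DMN": 5, "FPN": 4, "DAN": 4, "VAN": 3, "other": 4}
        )
        for label in RSN_NAMES:
            eff, cc = subnetwork_metrics(m, part, label)
            sub = m.submatrix(part.members(label))
            assert eff == pytest.approx(global_efficiency(sub), abs=1e-12)
            assert cc == pytest.approx(clustering_coefficient(sub)[1], abs=1e-12)
            assert eff == pytest.approx(
                floyd_warshall_efficiency(
                    np.where(np.eye(len(part.members(label))) == 1, 0, sub.values)
                ),
                abs=1e-10,
            )

    def test_unknown_label_rejected(self, rng):
        m, part = _partitioned_matrix(rng, {"DMN": 4, "FPN": 4, "DAN": 4, "VAN": 4})
        with pytest.raises(ValueError, match="unknown subnetwork"):
            subnetwork_metrics(m, part, "other")


class TestBlockFC:
    def test_constant_matrix_gives_constant_blocks(self):
        labels = {f"n{i}": name for i, name in enumerate(
            ["DMN"] * 3 + ["FPN"] * 3 + ["DAN"] * 3 + ["VAN"] * 3
        )}
        w = np.full((12, 12), 0.4)
        np.fill_diagonal(w, 1.0)
        m = CoherenceMatrix(w, list(labels))
        part = NetworkPartition(labels)
        within = within_network_fc(m, part)
        between = between_network_fc(m, part)
        assert len(between) == 6
        assert all(v == pytest.approx(0.4) for v in within.values())
        assert all(v == pytest.approx(0.4) for v in between.values())

    def test_hand_computed_two_network_example(self):
        # 5 nodes: A = {a0, a1}, B = {b0, b1, b2}; matrix fixed by hand
        labels = {"a0": "DMN", "a1": "DMN", "b0": "FPN", "b1": "FPN", "b2": "FPN"}
        w = np.array(
            [
                [1.0, 0.8, 0.1, 0.2, 0.3],
                [0.8, 1.0, 0.4, 0.5, 0.6],
                [0.1, 0.4, 1.0, 0.7, 0.2],
                [0.2, 0.5, 0.7, 1.0, 0.9],
                [0.3, 0.6, 0.2, 0.9, 1.0],
            ]
        )
        m = CoherenceMatrix(w, list(labels))
        part = NetworkPartition(labels)
        within = within_network_fc(m, part, labels=("DMN", "FPN"))
        # within DMN: single pair (a0,a1) = 0.8
        assert within["DMN"] == pytest.approx(0.8)
        # within FPN: pairs (b0,b1)=0.7, (b0,b2)=0.2, (b1,b2)=0.9 -> 0.6
        assert within["FPN"] == pytest.approx(0.6)
        between = between_network_fc(m, part, labels=("DMN", "FPN"))
        # cross block: 0.1+0.2+0.3+0.4+0.5+0.6 = 2.1 over 6 pairs
        assert between[("DMN", "FPN")] == pytest.approx(2.1 / 6)

    def test_symmetric_in_pair_order(self, rng):
        m, part = _partitioned_matrix(rng, {"DMN": 4, "FPN": 4, "DAN": 3, "VAN": 3})
        between = between_network_fc(m, part)
        ia = [i for i, n in enumerate(m.node_ids) if part.labels[n] == "FPN"]
        ib = [i for i, n in enumerate(m.node_ids) if part.labels[n] == "DMN"]
        swapped = float(m.values[np.ix_(ia, ib)].mean())
        assert between[("DMN", "FPN")] == pytest.approx(swapped)


class TestMetricsTable:
    def test_full_metric_set_shape_and_permutation_invariance(self, rng):
        m, part = _partitioned_matrix(
            rng, {"DMN": 4, "FPN": 4, "DAN": 4, "VAN": 4, "other": 4}
        )
        tm = compute_topology_metrics(m, part)
        assert len(tm.between_fc) == 6
        assert len(tm.within_fc) == 4
        assert np.isfinite(tm.global_efficiency)
        table = metrics_table({"s1": tm})
        assert table.shape == (1, 1 + 2 + 8 + 4 + 6)
        perm = rng.permutation(m.n_nodes)
        m2 = CoherenceMatrix(
            m.values[np.ix_(perm, perm)], [m.node_ids[p] for p in perm]
        )
        tm2 = compute_topology_metrics(m2, part)
        assert tm2.global_efficiency == pytest.approx(tm.global_efficiency, abs=1e-12)
        assert tm2.global_clustering == pytest.approx(tm.global_clustering, abs=1e-12)
        for name in RSN_NAMES:
            assert tm2.rsn_efficiency[name] == pytest.approx(tm.rsn_efficiency[name], abs=1e-12)
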