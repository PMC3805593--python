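from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasenet.network import (
    WeightedNetwork,
    betweenness,
    char_path_length,
    compute_metrics,
    global_clustering,
    nodal_clustering,
    random_ensemble,
    shortest_paths,
    small_worldness,
    threshold_topk,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (exhaustive enumeration, small graphs only)
# ---------------------------------------------------------------------------

def oracle_clustering(w: np.ndarray) -> np.ndarray:
    wmax = w.max()
    n = w.shape[0]
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j, h in combinations(nbrs, 2):
            total += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (1 / 3)
        out[i] = 2 * total / (k * (k - 1))
    return out


def _all_simple_paths(w, src, dst):
    n = w.shape[0]
    others = [v for v in range(n) if v not in (src, dst)]
    for r in range(len(others) + 1):
        for mid in permutations(others, r):
            path = (src, *mid, dst)
            if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                yield path


def oracle_shortest(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i, j in combinations(range(n), 2):
        best = np.inf
        for path in _all_simple_paths(w, i, j):
            best = min(best, sum(1.0 / w[a, b] for a, b in zip(path, path[1:])))
        dist[i, j] = dist[j, i] = best
    return dist


def oracle_betweenness(w: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for j, k in combinations(range(n), 2):
        lengths_paths = [
            (sum(1.0 / w[a, b] for a, b in zip(p, p[1:])), p)
            for p in _all_simple_paths(w, j, k)
        ]
        if not lengths_paths:
            continue
        best = min(length for length, _ in lengths_paths)
        shortest = [p for length, p in lengths_paths if length <= best + tol]
        for i in range(n):
            if i in (j, k):
                continue
            through = sum(1 for p in shortest if i in p)
            out[i] += through / len(shortest)
    return out


def random_weighted_graph(rng, n=None, p=0.5):
    n = n or rng.integers(4, 8)
    w = np.zeros((n, n))
    for i, j in combinations(range(int(n)), 2):
        if rng.random() < p:
            w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
    return w


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

class TestThresholdTopk:
    def test_default_k_90_edges(self, rng):
        mat = rng.uniform(0.01, 1, (28, 28))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        net = threshold_topk(mat, 90)
        assert net.n_edges == 90

    def test_full_k_keeps_everything(self, rng):
        mat = rng.uniform(0.01, 1, (5, 5))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        net = threshold_topk(mat, 10)
        assert np.allclose(net.weights, mat)

    def test_matches_sort_oracle(self, rng):
        mat = rng.uniform(0.01, 1, (4, 4))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        net = threshold_topk(mat, 3)
        pairs = sorted(combinations(range(4), 2), key=lambda p: -mat[p])
        for i, j in pairs[:3]:
            assert net.weights[i, j] == mat[i, j]
        for i, j in pairs[3:]:
            assert net.weights[i, j] == 0

    def test_tie_break_lexicographic(self):
        mat = np.full((3, 3), 0.5)
        np.fill_diagonal(mat, 0)
        net = threshold_topk(mat, 2)
        assert net.weights[0, 1] == 0.5 and net.weights[0, 2] == 0.5
        assert net.weights[1, 2] == 0.0

    def test_k_out_of_range(self, rng):
        mat = np.zeros((4, 4))
        with pytest.raises(ValueError, match="out of range"):
            threshold_topk(mat, 0)
        with pytest.raises(ValueError, match="out of range"):
            threshold_topk(mat, 7)

    @given(seed=st.integers(0, 500), k=st.integers(1, 10))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed, k):
        rng = np.random.default_rng(seed)
        mat = rng.uniform(0.01, 1, (6, 6))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        once = threshold_topk(mat, k)
        twice = threshold_topk(once.weights, k)
        assert np.array_equal(once.weights, twice.weights)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClustering:
    def test_unit_triangle(self):
        w = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        assert np.allclose(nodal_clustering(w), 1.0)

    def test_unit_path_no_triangles(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert np.allclose(nodal_clustering(w), 0.0)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            w = random_weighted_graph(rng)
            assert np.allclose(nodal_clustering(w), oracle_clustering(w), atol=1e-12)

    def test_global_mean_includes_zero_degree_nodes(self):
        assert global_clustering(np.array([1.0, 0.0, 0.0])) == pytest.approx(1 / 3)
        assert global_clustering(np.full(4, 0.5)) == 0.5

    def test_global_empty_rejected(self):
        with pytest.raises(ValueError):
            global_clustering(np.array([]))


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------

class TestShortestPaths:
    def test_reciprocal_weight(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        assert shortest_paths(w)[0, 1] == pytest.approx(2.0)

    def test_three_node_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        d = shortest_paths(w)
        assert d[0, 1] == 1 and d[1, 2] == 1 and d[0, 2] == 2

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            w = random_weighted_graph(rng, n=6)
            assert np.allclose(shortest_paths(w), oracle_shortest(w), atol=1e-10)


class TestCharPathLength:
    def test_three_node_unit_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        l, unreachable = char_path_length(shortest_paths(w))
        assert l == pytest.approx(4 / 3)
        assert unreachable == 0

    def test_complete_unit_graph(self):
        n = 6
        w = np.ones((n, n)) - np.eye(n)
        l, _ = char_path_length(shortest_paths(w))
        assert l == pytest.approx(1.0)

    def test_isolated_node_excluded_and_counted(self):
        # triangle plus an isolated 4th node: 3 reachable pairs, 3 unreachable
        w = np.zeros((4, 4))
        for i, j in ((0, 1), (1, 2), (0, 2)):
            w[i, j] = w[j, i] = 1.0
        l, unreachable = char_path_length(shortest_paths(w))
        assert l == pytest.approx(1.0)
        assert unreachable == 3

    def test_no_reachable_pairs(self):
        l, unreachable = char_path_length(shortest_paths(np.zeros((3, 3))))
        assert np.isnan(l) and unreachable == 3


# ---------------------------------------------------------------------------
# betweenness
# ---------------------------------------------------------------------------

class TestBetweenness:
    def test_star_center(self):
        w = np.zeros((4, 4))
        for leaf in (1, 2, 3):
            w[0, leaf] = w[leaf, 0] = 1.0
        b = betweenness(w)
        assert b[0] == pytest.approx(3.0)
        assert np.allclose(b[1:], 0.0)

    def test_unit_cycle_of_four(self):
        # opposite pairs have two equal shortest paths -> 1/2 through each node
        w = np.zeros((4, 4))
        for i, j in ((0, 1), (1, 2), (2, 3), (3, 0)):
            w[i, j] = w[j, i] = 1.0
        assert np.allclose(betweenness(w), 0.5)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            w = random_weighted_graph(rng)
            assert np.allclose(betweenness(w), oracle_betweenness(w), atol=1e-10)

    def test_agrees_with_networkx(self, rng):
        w = random_weighted_graph(rng, n=7, p=0.6)
        g = nx.from_numpy_array(np.where(w > 0, 1.0 / np.where(w > 0, w, 1), 0))
        ref = nx.betweenness_centrality(g, weight="weight", normalized=False)
        assert np.allclose(betweenness(w), [ref[i] for i in range(7)], atol=1e-9)

    def test_low_degree_nodes_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert np.allclose(betweenness(w), 0.0)


# ---------------------------------------------------------------------------
# ensemble and sigma
# ---------------------------------------------------------------------------

def _ring_lattice(n=20, k=4):
    g = nx.watts_strogatz_graph(n, k, 0.0, seed=1)
    w = nx.to_numpy_array(g)
    return WeightedNetwork(weights=w, k=g.number_of_edges())


class TestRandomEnsemble:
    def test_surrogates_preserve_edge_count_and_weights(self, rng):
        mat = rng.uniform(0.01, 1, (10, 10))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        net = threshold_topk(mat, 15)

        import phasenet.network as netmod
        captured = []
        orig = netmod.nodal_clustering

        def capture(w):
            if not isinstance(w, WeightedNetwork):
                captured.append(np.asarray(w).copy())
            return orig(w)

        netmod.nodal_clustering, netmod_restore = capture, orig
        try:
            random_ensemble(net, n_nets=5, seed=0)
        finally:
            netmod.nodal_clustering = netmod_restore
        original_weights = sorted(v for _, _, v in net.edges())
        for w in captured:
            iu = np.triu_indices(10, k=1)
            vals = w[iu][w[iu] > 0]
            assert len(vals) == 15
            assert np.allclose(sorted(vals), original_weights)

    def test_ring_lattice_clustering_drops(self):
        net = _ring_lattice()
        c_lattice = global_clustering(nodal_clustering(net))
        c_rand, _ = random_ensemble(net, n_nets=20, seed=3)
        assert c_rand < c_lattice / 2

    def test_requires_positive_count(self, rng):
        net = _ring_lattice()
        with pytest.raises(ValueError):
            random_ensemble(net, n_nets=0)


class TestSmallWorldness:
    def test_arithmetic(self):
        assert small_worldness(0.4, 2.0, 0.2, 2.0) == pytest.approx(2.0)

    def test_self_ensemble_is_one(self):
        assert small_worldness(0.3, 1.7, 0.3, 1.7) == pytest.approx(1.0)

    def test_watts_strogatz_sigma_above_one(self):
        g = nx.watts_strogatz_graph(28, 6, 0.1, seed=42)
        net = WeightedNetwork(weights=nx.to_numpy_array(g), k=g.number_of_edges())
        m = compute_metrics(net, n_rand=20, seed=0)
        assert m.sigma > 1.0

    def test_undefined_flagged(self):
        assert np.isnan(small_worldness(0.0, 1.0, 0.2, 1.0))
        assert np.isnan(small_worldness(0.3, np.inf, 0.2, 1.0))


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

class TestScalingInvariance:
    @given(scale=st.floats(0.1, 10), seed=st.integers(0, 200))
    @settings(max_examples=20, deadline=None)
    def test_metrics_under_weight_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, n=6, p=0.6)
        assert np.allclose(nodal_clustering(w * scale), nodal_clustering(w))
        assert np.allclose(betweenness(w * scale), betweenness(w), atol=1e-9)
        l1, _ = char_path_length(shortest_paths(w))
        l2, _ = char_path_length(shortest_paths(w * scale))
        if np.isfinite(l1):
            assert l2 == pytest.approx(l1 / scale)


def test_complete_unit_graph_metrics():
    n = 6
    w = np.ones((n, n)) - np.eye(n)
    net = WeightedNetwork(weights=w, k=n * (n - 1) // 2)
    m = compute_metrics(net, with_sigma=False)
    assert m.global_clustering == pytest.approx(1.0)
    assert m.char_path_length == pytest.approx(1.0)
    assert np.allclose(m.nodal_betweenness, 0.0)
    assert m.n_unreachable_pairs == 0


class TestWeightedNetworkValidation:
    def test_rejects_negative(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = -1
        with pytest.raises(ValueError, match="nonnegative"):
            WeightedNetwork(weights=w, k=1)

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            WeightedNetwork(weights=np.eye(3), k=1)
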