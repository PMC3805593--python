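"""Weighted-network construction and graph metrics.

An association matrix becomes a weighted network by keeping its ``k``
largest off-diagonal weights (the paper's proportional threshold).  On
that network we compute the weighted nodal clustering coefficient
(Onnela geometric-mean form, weights scaled by the network maximum),
the characteristic path length with reciprocal-weight edge lengths,
unnormalized weighted betweenness, and the small-worldness index
against an ensemble of degree-preserving random surrogates.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "WeightedNetwork",
    "NetworkMetrics",
    "threshold_topk",
    "nodal_clustering",
    "global_clustering",
    "shortest_paths",
    "char_path_length",
    "betweenness",
    "random_ensemble",
    "small_worldness",
    "compute_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative weight matrix with exactly ``k`` edges."""

    weights: np.ndarray
    k: int
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edges(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return [(int(a), int(b), float(self.weights[a, b])) for a, b in zip(i, j)]


@dataclass
class NetworkMetrics:
    """Nodal and global graph parameters of one network."""

    nodal_clustering: np.ndarray
    global_clustering: float
    char_path_length: float
    nodal_betweenness: np.ndarray
    n_unreachable_pairs: int
    c_rand: float = np.nan
    l_rand: float = np.nan
    sigma: float = np.nan


def threshold_topk(matrix, k: int, context: dict | None = None) -> WeightedNetwork:
    """Keep the ``k`` largest off-diagonal weights, zero the rest.

    Ties at the k-th weight break deterministically by lexicographic
    (row, column) order of the pair.  Original values are retained for
    selected edges.
    """
    psi = getattr(matrix, "psi", matrix)
    psi = np.asarray(psi, dtype=float)
    n = psi.shape[0]
    max_k = n * (n - 1) // 2
    if not 1 <= k <= max_k:
        raise ValueError(f"k={k} out of range [1, {max_k}] for {n} nodes")
    iu, ju = np.triu_indices(n, k=1)
    vals = psi[iu, ju]
    if np.isnan(vals).any():
        raise ValueError("association matrix contains NaN entries")
    # stable sort on (-weight, row, col): lexsort keys are last-key-major
    order = np.lexsort((ju, iu, -vals))[:k]
    w = np.zeros_like(psi)
    w[iu[order], ju[order]] = vals[order]
    w = w + w.T
    return WeightedNetwork(weights=w, k=k, context=context or {})


def nodal_clustering(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient per node.

    Weights are first scaled by the largest weight in the network; node
    ``i`` with binary degree ``k_i >= 2`` gets the geometric-mean
    triangle intensity ``sum_{j,h} (w_ij w_ih w_jh)^(1/3) /
    (k_i (k_i - 1))``; nodes of degree < 2 get 0.
    """
    w = net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, dtype=float)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    w_hat = np.cbrt(w / wmax)
    triangles = np.diag(w_hat @ w_hat @ w_hat)  # ordered (j, h) pairs
    degree = np.count_nonzero(w, axis=1)
    denom = degree * (degree - 1)
    out = np.zeros(w.shape[0])
    ok = denom > 0
    out[ok] = triangles[ok] / denom[ok]
    return out


def global_clustering(nodal: np.ndarray) -> float:
    """Arithmetic mean of nodal clustering over all nodes (zeros included)."""
    nodal = np.asarray(nodal, dtype=float)
    if nodal.size == 0:
        raise ValueError("empty nodal clustering vector")
    return float(nodal.mean())


def shortest_paths(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge length = 1 / weight.

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    w = net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, dtype=float)
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return dijkstra(csr_matrix(lengths), directed=False)


def char_path_length(distances: np.ndarray) -> tuple[float, int]:
    """Mean shortest path length over reachable unordered pairs.

    Returns ``(L, n_unreachable_pairs)``; unreachable pairs are excluded
    from the mean and counted.  With no reachable pair at all L is NaN.
    """
    d = np.asarray(distances, dtype=float)
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    unreachable = int(np.isinf(vals).sum())
    reachable = vals[np.isfinite(vals)]
    if reachable.size == 0:
        logger.warning("char_path_length: no reachable pairs; L undefined")
        return float("nan"), unreachable
    return float(reachable.mean()), unreachable


def _adjacency(w: np.ndarray) -> list[list[tuple[int, float]]]:
    n = w.shape[0]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        for j in np.nonzero(w[i])[0]:
            adj[i].append((int(j), 1.0 / w[i, j]))
    return adj


def betweenness(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness (Brandes' algorithm).

    For each node ``i``: sum over unordered pairs ``(j, k)``, both
    different from ``i``, of the fraction of minimal-length paths (edge
    length = 1/weight) between ``j`` and ``k`` that pass through ``i``.
    Unreachable pairs contribute 0.
    """
    w = net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, dtype=float)
    n = w.shape[0]
    adj = _adjacency(w)
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s], sigma[s] = 0.0, 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        stack: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            stack.append(u)
            for v, length in adj[u]:
                alt = d + length
                if alt < dist[v] - 1e-15:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (alt, v))
                elif abs(alt - dist[v]) <= 1e-15 and not done[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(stack):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    return bc / 2.0  # each unordered pair visited from both endpoints


def random_ensemble(net: WeightedNetwork, n_nets: int = 20,
                    seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Ensemble means (C_rand, L_rand) of size-matched random networks.

    Each surrogate preserves node count, edge count and (when the
    rewiring succeeds) the degree sequence via Maslov-Sneppen double
    edge swaps; the original multiset of edge weights is then randomly
    permuted onto the rewired edges.  If rewiring is impossible the
    surrogate falls back to an Erdos-Renyi graph with matched edge
    count (logged).
    """
    if n_nets < 1:
        raise ValueError("n_nets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = net.edges()
    m = len(edges)
    n = net.n_nodes
    weights = np.array([e[2] for e in edges])
    g0 = nx.Graph()
    g0.add_nodes_from(range(n))
    g0.add_edges_from((i, j) for i, j, _ in edges)

    cs, ls = [], []
    for _ in range(n_nets):
        g = g0.copy()
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            nx.double_edge_swap(g, nswap=10 * m, max_tries=1000 * m, seed=sub_seed)
        except nx.NetworkXError:
            logger.warning("random_ensemble: rewiring failed, Erdos-Renyi fallback")
            g = nx.gnm_random_graph(n, m, seed=sub_seed)
        perm = rng.permutation(m)
        w = np.zeros((n, n))
        for (u, v), wi in zip(g.edges(), weights[perm]):
            w[u, v] = w[v, u] = wi
        cs.append(global_clustering(nodal_clustering(w)))
        ls.append(char_path_length(shortest_paths(w))[0])
    return float(np.mean(cs)), float(np.nanmean(ls))


def small_worldness(c: float, l: float, c_rand: float, l_rand: float) -> float:
    """Small-worldness index sigma = (C / C_rand) / (L / L_rand)."""
    if min(c, l, c_rand, l_rand) <= 0 or not all(
            np.isfinite(x) for x in (c, l, c_rand, l_rand)):
        logger.warning("small_worldness undefined for c=%s l=%s c_rand=%s l_rand=%s",
                       c, l, c_rand, l_rand)
        return float("nan")
    return (c / c_rand) / (l / l_rand)


def compute_metrics(net: WeightedNetwork, n_rand: int = 20,
                    seed: int | np.random.Generator = 0,
                    with_sigma: bool = True) -> NetworkMetrics:
    """All nodal and global parameters of one thresholded network."""
    nodal_c = nodal_clustering(net)
    c = global_clustering(nodal_c)
    l, n_unreach = char_path_length(shortest_paths(net))
    bc = betweenness(net)
    c_rand = l_rand = sigma = float("nan")
    if with_sigma:
        c_rand, l_rand = random_ensemble(net, n_nets=n_rand, seed=seed)
        sigma = small_worldness(c, l, c_rand, l_rand)
    return NetworkMetrics(
        nodal_clustering=nodal_c,
        global_clustering=c,
        char_path_length=l,
        nodal_betweenness=bc,
        n_unreachable_pairs=n_unreach,
        c_rand=c_rand,
        l_rand=l_rand,
        sigma=sigma,
    )
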