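"""Weighted betweenness centrality, BC rank order, and average shortest path
length on full weighted connectivity graphs.

Stronger functional connections are treated as shorter paths: each Fisher-Z
edge weight z is inverted to a distance before Dijkstra-based shortest-path
computation. Because Dijkstra requires non-negative distances while a full
Fisher-Z graph contains negative edges, the inversion policy is explicit:

``exclude_nonpositive`` (default)
    d = 1/z for z > 0; non-positive edges get distance +inf (removed from
    path computations). Preserves the stronger-is-shorter ordering without
    reinterpreting anticorrelation.
``absolute``
    d = 1/|z| (z = 0 -> +inf). Treats correlation magnitude as coupling
    strength regardless of sign.
``clip_epsilon``
    z floored at 1e-6, then inverted; every edge stays finite.

Definitions (n = node count):

    BC_i  = 1/((n-1)(n-2)) * sum over ordered pairs (h, j), h != j != i,
            of sp_hj(i) / sp_hj          -- fraction of shortest paths via i
    ASPL  = 1/(n(n-1)) * sum over ordered pairs of d(v_i, v_j)

Node rank order (BC_RO) ranks nodes 1..n by descending BC, average rank on
ties, so rank 1 is the most central node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.stats import rankdata

from monoconn.connectivity import ConnectivityGraph

DistancePolicy = Literal["exclude_nonpositive", "absolute", "clip_epsilon"]
CLIP_EPSILON = 1e-6
POLICIES = ("exclude_nonpositive", "absolute", "clip_epsilon")


@dataclass
class DistanceGraph:
    """Pairwise edge distances derived from a connectivity graph.

    ``distances`` is n x n, symmetric, +inf on excluded edges, 0 diagonal.
    """

    distances: np.ndarray
    policy: str

    @property
    def n_nodes(self) -> int:
        return self.distances.shape[0]

    def shortest_paths(self) -> np.ndarray:
        """All-pairs Dijkstra shortest-path length matrix (+inf if unreachable)."""
        finite = np.where(np.isfinite(self.distances), self.distances, 0.0)
        mask = np.isfinite(self.distances) & (self.distances > 0)
        # csgraph treats explicit zeros as absent edges; pass a masked matrix
        from scipy.sparse import csr_matrix

        graph = csr_matrix((finite[mask], np.nonzero(mask)), shape=self.distances.shape)
        return _csgraph_dijkstra(graph, directed=False)


@dataclass
class CentralityProfile:
    """Per-node weighted BC in [0, 1] plus its descending rank order."""

    bc: np.ndarray
    bc_ro: np.ndarray
    policy: str


def to_distances(
    g: ConnectivityGraph, policy: DistancePolicy = "exclude_nonpositive"
) -> DistanceGraph:
    """Invert edge weights into path distances under the given policy."""
    z = g.weights.copy()
    if policy == "exclude_nonpositive":
        with np.errstate(divide="ignore"):
            d = np.where(z > 0, 1.0 / np.where(z > 0, z, 1.0), np.inf)
    elif policy == "absolute":
        az = np.abs(z)
        with np.errstate(divide="ignore"):
            d = np.where(az > 0, 1.0 / np.where(az > 0, az, 1.0), np.inf)
    elif policy == "clip_epsilon":
        d = 1.0 / np.maximum(z, CLIP_EPSILON)
    else:
        raise ValueError(f"unknown distance policy {policy!r}; expected {POLICIES}")
    np.fill_diagonal(d, 0.0)
    return DistanceGraph(d, policy=policy)


def _distance_nx_graph(dist: DistanceGraph) -> nx.Graph:
    n = dist.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    i, j = np.triu_indices(n, k=1)
    finite = np.isfinite(dist.distances[i, j])
    G.add_weighted_edges_from(
        zip(i[finite].tolist(), j[finite].tolist(), dist.distances[i, j][finite]),
        weight="distance",
    )
    return G


def betweenness(
    g: ConnectivityGraph, policy: DistancePolicy = "exclude_nonpositive"
) -> CentralityProfile:
    """Weighted betweenness centrality of every node, with rank order.

    Normalization is by the (n-1)(n-2) ordered pairs of distinct endpoints
    excluding the interior node, so BC lies in [0, 1]; node pairs with no
    finite path contribute nothing.
    """
    n = g.n_nodes
    if n < 3:
        raise ValueError(
            f"betweenness normalization 1/((n-1)(n-2)) is undefined for n={n} < 3"
        )
    dist = to_distances(g, policy)
    G = _distance_nx_graph(dist)
    bc_map = nx.betweenness_centrality(G, normalized=True, weight="distance")
    bc = np.array([bc_map[i] for i in range(n)])
    return CentralityProfile(bc=bc, bc_ro=rank_order(bc), policy=policy)


def rank_order(bc: np.ndarray) -> np.ndarray:
    """Descending ranks 1..n (1 = highest BC); tied values get average ranks."""
    return rankdata(-np.asarray(bc, dtype=float), method="average")


def aspl(
    g: ConnectivityGraph,
    policy: DistancePolicy = "exclude_nonpositive",
    return_finite_fraction: bool = False,
):
    """Average shortest path length over all ordered node pairs.

    Pairs with no finite path are excluded from the average (their count is
    available via ``return_finite_fraction``); a graph with no finite pair
    at all raises ``ValueError``.
    """
    if g.n_nodes < 2:
        raise ValueError("ASPL requires at least 2 nodes")
    dist = to_distances(g, policy)
    sp = dist.shortest_paths()
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("graph is fully disconnected: no finite shortest path")
    value = float(sp[finite].mean())
    if return_finite_fraction:
        return value, n_finite / (n * (n - 1))
    return value
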