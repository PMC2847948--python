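"""Structural modularity of gene networks.

The signed, directed genotype is projected onto an unweighted, undirected
simple graph (signs and directions ignored, reciprocal interactions
collapsed, self-interactions dropped).  Modularity of a partition into
non-overlapping modules is Newman's

    Q = sum_s [ l_s / L  -  (d_s / 2L)^2 ],

with ``L`` the total edge count, ``l_s`` the edges internal to module ``s``
and ``d_s`` the degree sum of its nodes.  Because the attainable Q depends
strongly on size and degree sequence, networks are compared on the
normalized score

    Qm = (Q - <Q_rand>) / (max Q_rand - <Q_rand>),

where the null ensemble consists of degree-preserving randomizations of the
graph (double-edge swaps), each scored with the same partition search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import networkx as nx
import numpy as np

from . import _kernels
from .core import GeneNetwork

__all__ = [
    "Partition",
    "ModularityResult",
    "project_to_graph",
    "modularity_score",
    "find_best_partition",
    "exhaustive_best_partition",
    "rewire_preserving_degrees",
    "null_q_statistics",
    "normalized_modularity",
]


class EdgelessGraphError(ValueError):
    """Raised when modularity is requested for a graph without edges."""


@dataclass
class Partition:
    """Assignment of each node to exactly one module.

    Labels are contiguous ``0..n_modules-1``, numbered by first occurrence.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1 or lab.size == 0:
            raise ValueError("partition labels must be a nonempty 1-d vector")
        # canonicalize to first-occurrence order
        mapping: dict[int, int] = {}
        out = np.empty_like(lab)
        for i, l in enumerate(lab):
            out[i] = mapping.setdefault(int(l), len(mapping))
        self.labels = out

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1

    def modules(self) -> list[set[int]]:
        return [set(np.flatnonzero(self.labels == s).tolist()) for s in range(self.n_modules)]


@dataclass
class ModularityResult:
    """Best partition with its Q and (optionally) its normalized score."""

    partition: Partition
    q: float
    q_normalized: Optional[float] = None
    null_mean_q: Optional[float] = None
    null_max_q: Optional[float] = None
    n_null: int = 0


def _graph_arrays(graph: nx.Graph) -> Tuple[np.ndarray, np.ndarray, int]:
    n = graph.number_of_nodes()
    if sorted(graph.nodes()) != list(range(n)):
        raise ValueError("graph nodes must be integers 0..n-1")
    A = nx.to_numpy_array(graph, nodelist=range(n), dtype=np.int8)
    np.fill_diagonal(A, 0)
    A[A != 0] = 1
    deg = A.sum(axis=1).astype(np.int64)
    L = int(deg.sum() // 2)
    return A, deg, L


def _edge_array(graph: nx.Graph) -> np.ndarray:
    edges = np.array(
        [(min(u, v), max(u, v)) for u, v in graph.edges() if u != v], dtype=np.int64
    ).reshape(-1, 2)
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def project_to_graph(network: GeneNetwork) -> nx.Graph:
    """Undirected simple graph underlying the signed directed genotype.

    Nodes are genes; an edge {i, j} (i != j) exists whenever either
    direction carries a nonzero interaction.  Self-interactions are dropped.
    """
    w = network.interactions
    g = nx.Graph()
    g.add_nodes_from(range(network.n_genes))
    ii, jj = np.nonzero(w)
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i != j:
            g.add_edge(min(i, j), max(i, j))
    return g


def modularity_score(graph: nx.Graph, partition: Partition | np.ndarray) -> float:
    """Newman's Q of ``partition`` on ``graph`` (undirected, unweighted)."""
    A, deg, L = _graph_arrays(graph)
    if L == 0:
        raise EdgelessGraphError("modularity is undefined for a graph without edges")
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition, dtype=np.int64)
    if labels.shape[0] != A.shape[0]:
        raise ValueError("partition must assign a label to every node")
    return float(_kernels.q_of_labels(A, deg, np.int64(L), labels.astype(np.int64)))


def find_best_partition(graph: nx.Graph) -> ModularityResult:
    """Heuristic Q maximization: greedy agglomeration plus node-move and
    module-merge refinement from several deterministic starts.

    Tie-breaking is lowest-index-first throughout, so repeated calls return
    identical partitions.
    """
    A, deg, L = _graph_arrays(graph)
    if L == 0:
        raise EdgelessGraphError("modularity is undefined for a graph without edges")
    labels, q = _kernels.best_partition_kernel(A, deg, np.int64(L))
    return ModularityResult(partition=Partition(labels), q=float(q))


def exhaustive_best_partition(graph: nx.Graph, max_nodes: int = 12) -> ModularityResult:
    """Exact Q optimum by full set-partition enumeration (oracle, n <= 12)."""
    A, deg, L = _graph_arrays(graph)
    if L == 0:
        raise EdgelessGraphError("modularity is undefined for a graph without edges")
    n = A.shape[0]
    if n > max_nodes:
        raise ValueError(f"exhaustive search limited to {max_nodes} nodes, got {n}")
    edges = _edge_array(graph)
    labels, q = _kernels.exhaustive_best_kernel(edges, deg, n, np.int64(L))
    return ModularityResult(partition=Partition(labels), q=float(q))


def rewire_preserving_degrees(
    graph: nx.Graph, n_swaps: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> nx.Graph:
    """Random simple graph with the same degree sequence, via double-edge swaps.

    ``n_swaps`` counts swap *attempts* (default ``10 * L``); proposals that
    would create a self-loop or a duplicate edge are skipped.
    """
    rng = np.random.default_rng(rng)
    A, deg, L = _graph_arrays(graph)
    if L < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * L
    edges = _edge_array(graph)
    adj = A.copy()
    rand = rng.random((n_swaps, 3))
    _kernels.double_edge_swap_kernel(edges, adj, rand)
    out = nx.Graph()
    out.add_nodes_from(range(A.shape[0]))
    out.add_edges_from(map(tuple, edges.tolist()))
    return out


def null_q_statistics(
    graph: nx.Graph,
    n_null: int = 1000,
    rng: Optional[np.random.Generator] = None,
    swaps_per_edge: int = 10,
) -> Tuple[float, float, np.ndarray]:
    """(mean, max, all Q values) of the best partition over ``n_null``
    degree-preserving randomizations of ``graph``."""
    rng = np.random.default_rng(rng)
    A, deg, L = _graph_arrays(graph)
    if L == 0:
        raise EdgelessGraphError("modularity is undefined for a graph without edges")
    edges = _edge_array(graph)
    rand = rng.random((n_null, swaps_per_edge * L, 3))
    qs = _kernels.null_q_kernel(edges, A.shape[0], np.int64(L), rand)
    return float(qs.mean()), float(qs.max()), qs


def normalized_modularity(
    graph: nx.Graph,
    n_null: int = 1000,
    rng: Optional[np.random.Generator] = None,
    null_stats: Optional[Tuple[float, float]] = None,
) -> ModularityResult:
    """Best partition of ``graph`` with its normalized modularity Qm.

    ``null_stats`` may supply a precomputed (mean, max) null summary for the
    graph's degree sequence (the swap null distribution depends on the graph
    only through that sequence); otherwise ``n_null`` randomizations are
    scored here.  If the null max equals the null mean the normalization is
    degenerate and Qm is defined as 0.
    """
    res = find_best_partition(graph)
    if null_stats is not None:
        null_mean, null_max = null_stats
        n_used = n_null
    else:
        null_mean, null_max, _ = null_q_statistics(graph, n_null=n_null, rng=rng)
        n_used = n_null
    denom = null_max - null_mean
    if abs(denom) < 1e-15:
        qm = 0.0
    else:
        qm = (res.q - null_mean) / denom
    return ModularityResult(
        partition=res.partition,
        q=res.q,
        q_normalized=float(qm),
        null_mean_q=float(null_mean),
        null_max_q=float(null_max),
        n_null=n_used,
    )
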