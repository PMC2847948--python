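"""Synthetic inputs: target activity patterns and oracle graphs.

The study needs no external data.  Selection targets are bit patterns over
the genes, built here with prescribed shared/different structure:

* canonical pattern pairs for specialization (half the genes keep a shared
  state, the rest take pattern-specific states),
* random pairs with a minimum number of differing genes,
* a triple whose third pattern splits the concerted gene groups further,
* a quartet in which the fourth pattern recombines block states of
  previously evolved modules (co-option).

Named small graphs with exactly known optimal modularity serve as the test
surface for the partition search.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from .core import as_pattern, pattern_from_bits

__all__ = [
    "make_pattern_pair",
    "random_pattern",
    "random_pattern_pair",
    "fig_pair_patterns",
    "triple_patterns",
    "cooption_quartet",
    "canonical_quartet",
    "oracle_graphs",
    "random_oracle_graphs",
]


def make_pattern_pair(
    n_genes: int,
    k_differences: int,
    rng: Optional[np.random.Generator] = None,
    placement: str = "tail",
) -> Tuple[np.ndarray, np.ndarray]:
    """Pattern pair at Hamming distance exactly ``k_differences``.

    The first pattern alternates active/inactive (gene 0 active): targets
    with a balanced mix of states are reliably attainable under the
    gain/loss mutation operator, whereas extreme patterns such as all-active
    demand net positive input at every gene and adapt far more slowly.  The
    second pattern flips the last ``k_differences`` genes
    (``placement='tail'``, the canonical layout with shared genes first) or
    a random subset (``placement='random'``, needs ``rng``).
    """
    if not (1 <= k_differences <= n_genes):
        raise ValueError(f"k_differences must lie in [1, {n_genes}], got {k_differences}")
    first = np.array([1 if g % 2 == 0 else -1 for g in range(n_genes)], dtype=np.int8)
    second = first.copy()
    if placement == "tail":
        idx = np.arange(n_genes - k_differences, n_genes)
    elif placement == "random":
        if rng is None:
            raise ValueError("placement='random' needs an rng")
        idx = rng.choice(n_genes, size=k_differences, replace=False)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    second[idx] = -second[idx]
    return first, second


def random_pattern(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random pattern: each gene active or inactive equiprobably."""
    return np.where(rng.random(n_genes) < 0.5, 1, -1).astype(np.int8)


def random_pattern_pair(
    n_genes: int, min_differences: int = 2, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Two uniform random patterns, rejection-sampled until they differ at
    ``min_differences`` or more genes."""
    if min_differences < 1:
        raise ValueError("min_differences must be >= 1")
    if min_differences > n_genes:
        raise ValueError("min_differences cannot exceed n_genes")
    rng = np.random.default_rng(rng)
    while True:
        a = random_pattern(n_genes, rng)
        b = random_pattern(n_genes, rng)
        if int((a != b).sum()) >= min_differences:
            return a, b


def fig_pair_patterns(n_genes: int = 10) -> Tuple[np.ndarray, np.ndarray]:
    """Canonical specialization pair: pattern II shares the first half of
    the genes with pattern I and differs at the second half."""
    return make_pattern_pair(n_genes, n_genes // 2)


# Canonical triple for the third-pattern experiment.  Concerted groups across
# I and II are {0,1,2,5,6} (changing) and {3,4,7,8,9} (shared); adding III
# splits the changing group into {0,1,2} and {5,6}.  Genes 5 and 6 are
# anti-concerted in every pattern; genes 0 and 6 are concerted only while III
# is absent (and genes 0 and 8 only while II is absent).  III differs from II
# at exactly the {5,6} pair, so the third pattern is acquirable by shifting
# an existing basin rather than by building a distant attractor from nothing,
# and each pattern keeps a near-even mix of states.
_TRIPLE = ("1010101010", "0100110010", "0100101010")


def triple_patterns() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three 10-gene patterns whose third member splits the concerted gene
    groups of the first two (see module docstring)."""
    return tuple(pattern_from_bits(b) for b in _TRIPLE)  # type: ignore[return-value]


def cooption_quartet(
    n_genes: int = 10, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Patterns I, II, III plus a co-option target IV.

    The genes split into two half blocks A (first half) and B (second
    half).  Across I, II, III each block takes exactly two distinct block
    states (a1/a2 and b1/b2): I = (a1, b1), II = (a1, b2), III = (a2, b1).
    IV = (a2, b2) copies its A-block from III and its B-block from II, so it
    recombines previously selected module states, and it necessarily
    differs from each of I, II and III.
    """
    if n_genes % 2 != 0:
        raise ValueError("cooption_quartet needs an even number of genes")
    h = n_genes // 2
    rng = np.random.default_rng(rng)

    def two_block_states(size: int) -> Tuple[np.ndarray, np.ndarray]:
        s1 = random_pattern(size, rng)
        while True:
            s2 = random_pattern(size, rng)
            if (s1 != s2).any():
                return s1, s2

    a1, a2 = two_block_states(h)
    b1, b2 = two_block_states(h)
    I = np.concatenate([a1, b1])
    II = np.concatenate([a1, b2])
    III = np.concatenate([a2, b1])
    IV = np.concatenate([a2, b2])
    return I, II, III, IV


def canonical_quartet(n_genes: int = 10) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic co-option quartet built from complementary alternating
    half-block states (a1/a2 for the first block, b1/b2 for the second):
    I = (a1, b1), II = (a1, b2), III = (a2, b1), IV = (a2, b2).  For 10
    genes: I = 1010101010, II = 1010110101, III = 0101001010,
    IV = 0101010101 — every pattern a near-even mix of states."""
    if n_genes % 2 != 0:
        raise ValueError("canonical_quartet needs an even number of genes")
    h = n_genes // 2
    a1 = np.array([1 if g % 2 == 0 else -1 for g in range(h)], dtype=np.int8)
    a2 = -a1
    b1 = np.array([-1 if g % 2 == 0 else 1 for g in range(h)], dtype=np.int8)
    b2 = -b1
    return (
        np.concatenate([a1, b1]),
        np.concatenate([a1, b2]),
        np.concatenate([a2, b1]),
        np.concatenate([a2, b2]),
    )


def oracle_graphs() -> Dict[str, nx.Graph]:
    """Named graphs whose optimal Q is known from exhaustive search.

    ``two_k3`` and ``two_k4``: optimal partition = the two cliques, Q = 0.5;
    ``k5``: single module, Q = 0; ``path3``: 3-node path; ``bridged_k5``:
    two 5-cliques joined by one edge, optimal partition = the cliques.
    """
    graphs: Dict[str, nx.Graph] = {}
    two_k3 = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    graphs["two_k3"] = two_k3
    graphs["two_k4"] = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    graphs["k5"] = nx.complete_graph(5)
    graphs["path3"] = nx.path_graph(3)
    bridged = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    bridged.add_edge(4, 5)
    graphs["bridged_k5"] = bridged
    return graphs


def random_oracle_graphs(
    n_graphs: int = 50, seed: int = 20100326, sizes: Tuple[int, ...] = (8, 9, 10)
) -> List[Tuple[str, nx.Graph]]:
    """Seeded random graphs (Erdős–Rényi, 8-10 nodes, at least 2 edges) for
    oracle-equivalence checks of the partition search."""
    rng = np.random.default_rng(seed)
    out: List[Tuple[str, nx.Graph]] = []
    while len(out) < n_graphs:
        n = int(rng.choice(sizes))
        p = float(rng.uniform(0.15, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if g.number_of_edges() < 2:
            continue
        out.append((f"random_{len(out):02d}_n{n}", g))
    return out
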