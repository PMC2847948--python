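"""Robustness-aware fitness of gene networks.

A network is fit for a reference activity pattern if the dynamics carry
initial conditions *near* that pattern to a fixed point *matching* it.
Evaluation samples ``n_trajectories`` initial states, each a per-gene
perturbation of the target (flip probability ``flip_probability`` < 0.5,
so initial conditions stay biased towards the reference), runs each to its
attractor, and scores the trajectory

    gamma = (1 - D_H(A, target) / N) ** distance_exponent

for a fixed point ``A`` and gamma = 0 for a cyclic attractor (only stable
attainment counts).  The per-pattern fitness ``f`` is the mean gamma over
trajectories; with several selected patterns the network fitness ``F`` is
the arithmetic mean (additive, default) or the product (multiplicative) of
the per-pattern values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .core import GeneNetwork, as_pattern, find_attractor, hamming_distance

__all__ = [
    "FitnessParams",
    "FitnessValue",
    "sample_initial_state",
    "trajectory_contribution",
    "pattern_fitness",
    "network_fitness",
    "exact_pattern_fitness",
]


@dataclass
class FitnessParams:
    """Parameters of the sampled fitness estimator.

    Defaults follow the study conditions: 500 developmental trajectories per
    pattern, per-gene perturbation probability 0.15, distance exponent 5,
    additive combination across patterns.  ``max_steps`` of None means
    ``2**N`` for networks of up to 10 genes and 200 beyond that.
    """

    n_trajectories: int = 500
    flip_probability: float = 0.15
    distance_exponent: int = 5
    max_steps: Optional[int] = None
    combination: str = "additive"

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if not (0.0 <= self.flip_probability < 0.5):
            raise ValueError("flip_probability must lie in [0, 0.5): initial conditions "
                             "must stay biased towards the reference pattern")
        if self.distance_exponent < 1:
            raise ValueError("distance_exponent must be a positive integer")
        if self.combination not in ("additive", "multiplicative"):
            raise ValueError(f"unknown combination mode {self.combination!r}")

    def resolved_max_steps(self, n_genes: int) -> int:
        if self.max_steps is not None:
            return self.max_steps
        return 2 ** n_genes if n_genes <= 10 else 200


@dataclass
class FitnessValue:
    """Per-pattern fitnesses ``f`` and their combination ``F``."""

    per_pattern: Dict[int, float] = field(default_factory=dict)
    combined: float = 0.0


def sample_initial_state(target, flip_probability: float, rng: np.random.Generator) -> np.ndarray:
    """Perturbation of ``target``: each gene's state flips independently with
    probability ``flip_probability``."""
    t = as_pattern(target)
    flips = rng.random(t.shape[0]) < flip_probability
    out = t.copy()
    out[flips] = -out[flips]
    return out


def trajectory_contribution(network: GeneNetwork, target, initial, params: FitnessParams) -> float:
    """Fitness contribution of one developmental trajectory.

    ``(1 - D_H/N) ** exponent`` if a fixed point is reached, 0 for cycles.
    """
    t = as_pattern(target, network.n_genes)
    res = find_attractor(network, initial, max_steps=params.resolved_max_steps(network.n_genes))
    if res.kind != "fixed_point":
        return 0.0
    d = hamming_distance(res.fixed_state, t)
    return (1.0 - d / network.n_genes) ** params.distance_exponent


def pattern_fitness(
    network: GeneNetwork, target, params: FitnessParams, rng: np.random.Generator
) -> float:
    """Monte-Carlo per-pattern fitness: mean trajectory contribution over
    ``n_trajectories`` fresh perturbed initial conditions."""
    t = as_pattern(target, network.n_genes)
    total = 0.0
    for _ in range(params.n_trajectories):
        initial = sample_initial_state(t, params.flip_probability, rng)
        total += trajectory_contribution(network, t, initial, params)
    return total / params.n_trajectories


def network_fitness(
    network: GeneNetwork,
    targets: Sequence,
    params: FitnessParams,
    rng: np.random.Generator,
) -> FitnessValue:
    """Fitness over one or more selected patterns.

    Additive mode averages the per-pattern fitnesses (a network failing one
    new pattern can still contribute offspring); multiplicative mode takes
    their product.
    """
    if len(targets) == 0:
        raise ValueError("network_fitness needs at least one target pattern")
    per = {i: pattern_fitness(network, t, params, rng) for i, t in enumerate(targets)}
    vals = np.array(list(per.values()))
    combined = float(vals.mean()) if params.combination == "additive" else float(vals.prod())
    return FitnessValue(per_pattern=per, combined=combined)


def exact_pattern_fitness(network: GeneNetwork, target, params: FitnessParams) -> float:
    """Exact expectation of the per-pattern fitness (test oracle, N <= 12).

    Sums the trajectory contribution over all 2^N initial states weighted by
    their binomial perturbation probability; the Monte-Carlo estimator of
    :func:`pattern_fitness` converges to this value.
    """
    n = network.n_genes
    if n > 12:
        raise ValueError("exact enumeration limited to 12 genes")
    t = as_pattern(target, n)
    p = params.flip_probability
    total = 0.0
    for code in range(2 ** n):
        state = np.array([1 if (code >> j) & 1 else -1 for j in range(n)], dtype=np.int8)
        k = hamming_distance(state, t)
        weight = (p ** k) * ((1.0 - p) ** (n - k))
        total += weight * trajectory_contribution(network, t, state, params)
    return total
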