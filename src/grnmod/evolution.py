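"""Population-genetic simulation of gene-network evolution.

Populations of constant size evolve by fitness-proportional reproduction
(offspring sampled with replacement, probability f_j / sum f) followed by
mutation.  A mutating gene either loses one of its ``r`` regulators, with
probability

    p_loss(r) = 4r / (4r + (N - r)),

or gains a new one (sign ±1 equiprobable) in a currently empty cell of its
row.  This biased gain/loss operator drives networks towards the low
connectivities (2-3 regulators per gene) typical of transcriptional
regulation.  Selection regimes are ordered phases, each a generation count
plus a set of target activity patterns; an empty target set means neutral
evolution (uniform reproduction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _kernels
from .core import GeneNetwork, as_pattern
from .fitness import FitnessParams, network_fitness
from .modularity import Partition, find_best_partition, project_to_graph

__all__ = [
    "EvolutionParams",
    "Phase",
    "SelectionRegime",
    "PartitionSample",
    "EvolutionTrace",
    "founder_network",
    "loss_probability",
    "mutate_gene",
    "mutate_network",
    "next_generation",
    "evolve",
]


@dataclass
class EvolutionParams:
    """Population and mutation parameters (defaults: 10 genes, 20 founder
    interactions, 100 individuals, per-gene mutation probability 0.05)."""

    population_size: int = 100
    mu: float = 0.05
    n_genes: int = 10
    founder_edges: int = 20
    allow_self_interactions: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.n_genes < 1 or self.founder_edges < 1:
            raise ValueError("population_size, n_genes and founder_edges must be positive")
        if not (0.0 <= self.mu < 1.0):
            raise ValueError("mu must lie in [0, 1)")
        max_cells = self.n_genes ** 2 if self.allow_self_interactions else self.n_genes * (self.n_genes - 1)
        if self.founder_edges > max_cells:
            raise ValueError(
                f"founder_edges={self.founder_edges} exceeds the {max_cells} "
                "available cells of the interaction matrix"
            )


@dataclass
class Phase:
    """One selection phase: a generation count and the patterns favored
    during it (empty list = neutral evolution)."""

    n_generations: int
    targets: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        self.targets = [as_pattern(t) for t in self.targets]


@dataclass
class SelectionRegime:
    phases: List[Phase]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a selection regime needs at least one phase")

    @property
    def total_generations(self) -> int:
        return sum(p.n_generations for p in self.phases)


@dataclass
class PartitionSample:
    """Best-network partition sampled during a run (no null normalization)."""

    generation: int
    partition: Partition
    q: float

    @property
    def n_modules(self) -> int:
        return self.partition.n_modules


@dataclass
class EvolutionTrace:
    """Per-generation record of an evolving population.

    One record per generation including generation 0 (the founder-derived
    initial population).  Fitness entries are NaN during neutral phases.
    """

    generation: np.ndarray
    phase_index: np.ndarray
    max_fitness: np.ndarray
    mean_fitness: np.ndarray
    best_genotypes: np.ndarray  # (G+1, N, N) int8
    partition_samples: List[PartitionSample]
    population_size: int
    per_pattern_best: Optional[np.ndarray] = None  # (G+1, T_max) fitness of best net

    def __len__(self) -> int:
        return self.generation.size

    def best_network(self, generation: int = -1) -> GeneNetwork:
        return GeneNetwork(self.best_genotypes[generation].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "phase": self.phase_index,
                "max_fitness": self.max_fitness,
                "mean_fitness": self.mean_fitness,
            }
        )


def founder_network(params: EvolutionParams, rng: np.random.Generator) -> GeneNetwork:
    """Founder genotype: ``founder_edges`` distinct matrix cells set to ±1
    (equiprobable signs), positions uniform over all N² cells, so
    self-interactions are permitted."""
    n = params.n_genes
    pool = np.arange(n * n)
    if not params.allow_self_interactions:
        pool = pool[pool // n != pool % n]
    cells = rng.choice(pool, size=params.founder_edges, replace=False)
    w = np.zeros(n * n, dtype=np.int8)
    w[cells] = np.where(rng.random(params.founder_edges) < 0.5, 1, -1)
    return GeneNetwork(w.reshape(n, n))


def loss_probability(n_regulators: int, n_genes: int) -> float:
    """Probability that a mutation of a gene with ``n_regulators`` regulators
    deletes one of them rather than adding a new one."""
    r = n_regulators
    return 4.0 * r / (4.0 * r + (n_genes - r))


def _mutate_row(
    w: np.ndarray, gene: int, n: int, rng: np.random.Generator, allow_self: bool = True
) -> None:
    row = w[gene]
    regulators = np.flatnonzero(row)
    r = regulators.size
    empty = np.flatnonzero(row == 0)
    if not allow_self:
        empty = empty[empty != gene]
    # a full row (no gainable cell) forces a loss; r = 0 forces a gain
    if r > 0 and (empty.size == 0 or rng.random() < loss_probability(r, n)):
        row[regulators[rng.integers(r)]] = 0
    else:
        row[empty[rng.integers(empty.size)]] = 1 if rng.random() < 0.5 else -1


def mutate_gene(
    network: GeneNetwork, gene: int, rng: np.random.Generator,
    allow_self_interactions: bool = True,
) -> GeneNetwork:
    """One mutation event at ``gene``: delete one existing regulator (with
    probability ``p_loss``) or add one new signed interaction.  Exactly one
    cell of the gene's row changes."""
    if not (0 <= gene < network.n_genes):
        raise IndexError(f"gene index {gene} out of range")
    w = network.interactions.copy()
    _mutate_row(w, gene, network.n_genes, rng, allow_self=allow_self_interactions)
    return GeneNetwork(w)


def mutate_network(
    network: GeneNetwork, mu: float, rng: np.random.Generator,
    allow_self_interactions: bool = True,
) -> GeneNetwork:
    """Each gene independently undergoes one mutation event with probability
    ``mu``."""
    if not (0.0 <= mu <= 1.0):
        raise ValueError("mu must lie in [0, 1]")
    w = network.interactions.copy()
    n = network.n_genes
    for gene in np.flatnonzero(rng.random(n) < mu):
        _mutate_row(w, int(gene), n, rng, allow_self=allow_self_interactions)
    return GeneNetwork(w)


def next_generation(
    population: Sequence[GeneNetwork],
    fitnesses: Sequence[float],
    rng: np.random.Generator,
) -> List[GeneNetwork]:
    """Fitness-proportional sampling of the next generation (constant size,
    with replacement).  If all fitnesses are zero, parents are drawn
    uniformly so the population survives the onset of a hard new target.
    Mutation is applied afterwards by the caller."""
    if len(population) != len(fitnesses):
        raise ValueError("population and fitnesses must have equal length")
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    probs = None if total == 0 else f / total
    parents = rng.choice(len(population), size=len(population), replace=True, p=probs)
    return [population[i].copy() for i in parents]


class _FitnessEngine:
    """Population fitness via the compiled attractor kernel.

    Each genotype gets a flat (initial state -> fixed point) lookup table,
    cached across generations keyed by the genotype's matrix bytes —
    unmutated offspring and recurring genotypes reuse their parent's
    attractor map.  Falls back to the uncompiled reference path for
    networks beyond :data:`_kernels.MAX_KERNEL_GENES` genes.
    """

    #: cap on cached genotype tables (2^N int16 entries each)
    MAX_TABLES = 30_000

    def __init__(self, n_genes: int, params: FitnessParams):
        self.n = n_genes
        self.params = params
        self.compiled = n_genes <= _kernels.MAX_KERNEL_GENES
        if self.compiled:
            self.tables: dict[bytes, np.ndarray] = {}
            self.stamps = np.zeros(2 ** n_genes, dtype=np.int64)
            self.version = np.int64(0)

    def evaluate(
        self, pop: np.ndarray, targets: List[np.ndarray], rng: np.random.Generator
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Return (combined fitness (P,), per-pattern fitness (P, T))."""
        P = pop.shape[0]
        T = len(targets)
        params = self.params
        if not self.compiled:
            per = np.empty((P, T))
            for i in range(P):
                net = GeneNetwork(pop[i].copy())
                fv = network_fitness(net, targets, params, rng)
                per[i] = [fv.per_pattern[t] for t in range(T)]
        else:
            if len(self.tables) > self.MAX_TABLES:
                self.tables = {}
            tgt = np.stack(targets).astype(np.int8)
            flips = rng.random((P, T, params.n_trajectories, self.n), dtype=np.float32)
            p = params.flip_probability
            exponent = np.int64(params.distance_exponent)
            max_steps = np.int64(params.resolved_max_steps(self.n))
            per = np.empty((P, T))
            for i in range(P):
                key = pop[i].tobytes()
                table = self.tables.get(key)
                if table is None:
                    table = _kernels.new_attractor_table(self.n)
                    self.tables[key] = table
                per[i], self.version = _kernels.genotype_gammas(
                    pop[i], tgt, flips[i], p, exponent, max_steps,
                    table, self.stamps, self.version,
                )
        if params.combination == "additive":
            combined = per.mean(axis=1)
        else:
            combined = per.prod(axis=1)
        return combined, per


def _spawn_rngs(seed: Union[int, np.random.SeedSequence]) -> dict:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ("founder", "mutation", "selection", "fitness")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _mutate_population(
    pop: np.ndarray, mu: float, rng: np.random.Generator, allow_self: bool = True
) -> None:
    P, n = pop.shape[0], pop.shape[1]
    hits = rng.random((P, n)) < mu
    for i, gene in zip(*np.nonzero(hits)):
        _mutate_row(pop[i], int(gene), n, rng, allow_self=allow_self)


def evolve(
    regime: SelectionRegime,
    evo_params: EvolutionParams,
    fit_params: FitnessParams,
    seed: Union[int, np.random.SeedSequence],
    sample_interval: Optional[int] = 25,
    initial_population: Optional[np.ndarray] = None,
    return_population: bool = False,
):
    """Run one population through a selection regime.

    The founder network receives ``population_size`` copies, each passed
    through one round of per-gene mutation; every later generation is
    reproduction (fitness-proportional, or uniform in neutral phases)
    followed by mutation and fitness evaluation.  ``sample_interval`` sets
    how often the best network's module partition is recorded (phase
    boundaries are always sampled); None disables sampling.

    Randomness is split into independent substreams (founder, mutation,
    selection, fitness) derived from ``seed``, so identical seeds give
    bit-identical traces.  Returns an :class:`EvolutionTrace`, plus the
    final population array if ``return_population``.
    """
    rngs = _spawn_rngs(seed)
    n = evo_params.n_genes
    P = evo_params.population_size
    for phase in regime.phases:
        for t in phase.targets:
            if t.shape[0] != n:
                raise ValueError("target pattern length does not match n_genes")

    if initial_population is not None:
        pop = initial_population.astype(np.int8).copy()
        if pop.shape != (P, n, n):
            raise ValueError(f"initial population must have shape {(P, n, n)}")
    else:
        founder = founder_network(evo_params, rngs["founder"])
        pop = np.repeat(founder.interactions[None, :, :], P, axis=0).copy()
        _mutate_population(pop, evo_params.mu, rngs["mutation"],
                           allow_self=evo_params.allow_self_interactions)

    engine = _FitnessEngine(n, fit_params)

    gens: List[int] = []
    phases: List[int] = []
    max_f: List[float] = []
    mean_f: List[float] = []
    best_gt: List[np.ndarray] = []
    samples: List[PartitionSample] = []

    def evaluate(phase_idx: int) -> Tuple[np.ndarray, int]:
        targets = regime.phases[phase_idx].targets
        if targets:
            combined, _per = engine.evaluate(pop, targets, rngs["fitness"])
            best = int(np.argmax(combined))
        else:
            combined = np.full(P, np.nan)
            best = 0
        return combined, best

    def record(gen: int, phase_idx: int, combined: np.ndarray, best: int, at_boundary: bool) -> None:
        gens.append(gen)
        phases.append(phase_idx)
        max_f.append(float(np.nanmax(combined)) if not np.isnan(combined).all() else np.nan)
        mean_f.append(float(np.nanmean(combined)) if not np.isnan(combined).all() else np.nan)
        best_gt.append(pop[best].copy())
        due = sample_interval is not None and gen % sample_interval == 0
        if due or at_boundary:
            graph = project_to_graph(GeneNetwork(pop[best].copy()))
            if graph.number_of_edges() > 0:
                res = find_best_partition(graph)
                samples.append(PartitionSample(generation=gen, partition=res.partition, q=res.q))

    gen = 0
    first_phase = 0
    combined, best = evaluate(first_phase)
    record(gen, first_phase, combined, best, at_boundary=False)

    for phase_idx, phase in enumerate(regime.phases):
        neutral = not phase.targets
        if phase_idx > 0:
            # re-evaluate under the new phase's targets so that the first
            # round of selection in the phase already reflects them
            combined, best = evaluate(phase_idx)
        for _ in range(phase.n_generations):
            gen += 1
            if neutral or np.nansum(combined) == 0 or np.isnan(combined).all():
                parents = rngs["selection"].integers(0, P, size=P)
            else:
                probs = combined / combined.sum()
                parents = rngs["selection"].choice(P, size=P, replace=True, p=probs)
            pop = pop[parents].copy()
            _mutate_population(pop, evo_params.mu, rngs["mutation"],
                               allow_self=evo_params.allow_self_interactions)
            combined, best = evaluate(phase_idx)
            record(gen, phase_idx, combined, best, at_boundary=(_ == phase.n_generations - 1))

    trace = EvolutionTrace(
        generation=np.array(gens),
        phase_index=np.array(phases),
        max_fitness=np.array(max_f),
        mean_fitness=np.array(mean_f),
        best_genotypes=np.stack(best_gt),
        partition_samples=samples,
        population_size=P,
    )
    if return_population:
        return trace, pop
    return trace
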