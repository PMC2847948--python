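"""Replicated experiments and their statistics.

Drivers for the three study designs:

* specialization: populations first select one pattern, then that pattern
  plus new ones; normalized modularity Qm of the best networks is compared
  across phase boundaries with a one-sided Wilcoxon signed-rank test
  (controls — single pattern, all-genes-differ pairs, neutral evolution —
  run through the same driver by configuration alone),
* module composition: frequencies with which gene pairs of the
  shared/non-shared classes co-occur in one module of the best networks,
* co-option: after evolving patterns I+II+III, matched population pairs
  select either the module-recombining pattern IV or a random pattern, and
  the post-onset fitness trajectories are compared.

Null ensembles for Qm are cached by degree sequence: the double-edge-swap
null distribution depends on the graph only through its degree sequence,
and evolved networks concentrate on few sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core import GeneNetwork
from .evolution import (
    EvolutionParams,
    EvolutionTrace,
    Phase,
    SelectionRegime,
    evolve,
)
from .fitness import FitnessParams
from .fixtures import random_pattern
from .modularity import (
    ModularityResult,
    Partition,
    normalized_modularity,
    null_q_statistics,
    project_to_graph,
)

__all__ = [
    "PairedTestResult",
    "paired_signed_rank",
    "CoModuleFrequencies",
    "co_module_frequencies",
    "module_count_series",
    "NullStatsCache",
    "qm_of_network",
    "ExperimentConfig",
    "SpecializationResult",
    "run_specialization_experiment",
    "CooptionResult",
    "run_cooption_experiment",
]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (one-sided, exact for small n)
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    statistic: float  # W+: rank sum of positive differences
    z: float
    p_one_sided: float
    n_pairs: int
    exact: bool


def _exact_signed_rank_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under the exact null (all 2^n sign assignments
    equiprobable), via convolution over doubled ranks so midranks stay
    integral.  Equivalent to full enumeration."""
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2_obs = int(np.rint(2 * w_obs))  # doubling keeps midranks integral
    return float(counts[w2_obs:].sum() / counts.sum())


def paired_signed_rank(before: Sequence[float], after: Sequence[float]) -> PairedTestResult:
    """One-sided Wilcoxon signed-rank test of median(after - before) > 0.

    Zero differences are dropped, tied magnitudes midranked.  The null is
    exact (full sign enumeration) for n <= 25 and a normal approximation
    with continuity and tie correction above.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1 or b.size < 2:
        raise ValueError("before/after must be equal-length 1-d sequences of >= 2 values")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    var_w = float((ranks ** 2).sum()) / 4.0
    z = (w - mean_w - 0.5) / np.sqrt(var_w) if var_w > 0 else 0.0
    if n <= 25:
        p = _exact_signed_rank_sf(ranks, w)
        exact = True
    else:
        p = float(norm.sf(z))
        exact = False
    return PairedTestResult(statistic=w, z=float(z), p_one_sided=p, n_pairs=n, exact=exact)


# ---------------------------------------------------------------------------
# Module composition statistics
# ---------------------------------------------------------------------------


@dataclass
class CoModuleFrequencies:
    """Fractions of gene pairs co-assigned to one module, by pair class."""

    p_shared_shared: float
    p_nonshared_nonshared: float
    p_shared_nonshared: float
    generation: int = -1
    pairwise: Optional[pd.DataFrame] = None  # per-pair co-module frequency p_x,y


def co_module_frequencies(
    best_partitions: Sequence[Partition],
    shared_genes: Sequence[int],
    nonshared_genes: Sequence[int],
    generation: int = -1,
) -> CoModuleFrequencies:
    """Co-module frequencies over populations at one sampled generation.

    ``shared_genes`` hold the same activity state in every selected pattern;
    ``nonshared_genes`` change state (concertedly) between patterns.  For
    each class of unordered pairs the returned value is the fraction, over
    all populations and pairs, co-assigned to a single module.
    """
    shared = sorted(set(int(g) for g in shared_genes))
    nonshared = sorted(set(int(g) for g in nonshared_genes))
    if set(shared) & set(nonshared):
        raise ValueError("shared and non-shared gene sets must be disjoint")
    if not best_partitions:
        raise ValueError("need at least one partition")
    genes = shared + nonshared
    pair_hits: Dict[Tuple[int, int], float] = {
        pair: 0.0 for pair in combinations(sorted(genes), 2)
    }
    for part in best_partitions:
        lab = part.labels
        for x, y in pair_hits:
            if lab[x] == lab[y]:
                pair_hits[(x, y)] += 1.0
    n_pop = len(best_partitions)

    def class_mean(pairs: List[Tuple[int, int]]) -> float:
        if not pairs:
            return float("nan")
        return float(np.mean([pair_hits[tuple(sorted(p))] for p in pairs]) / n_pop)

    ss = list(combinations(shared, 2))
    nn = list(combinations(nonshared, 2))
    sn = [(x, y) for x in shared for y in nonshared]
    pairwise = pd.DataFrame(
        [(x, y, hits / n_pop) for (x, y), hits in sorted(pair_hits.items())],
        columns=["gene_x", "gene_y", "p_xy"],
    )
    return CoModuleFrequencies(
        p_shared_shared=class_mean(ss),
        p_nonshared_nonshared=class_mean(nn),
        p_shared_nonshared=class_mean(sn),
        generation=generation,
        pairwise=pairwise,
    )


def co_module_series(
    traces: Sequence[EvolutionTrace], shared_genes, nonshared_genes
) -> pd.DataFrame:
    """Co-module frequencies at every generation sampled in all traces."""
    common = None
    by_gen: Dict[int, List[Partition]] = {}
    for tr in traces:
        gens = {s.generation for s in tr.partition_samples}
        common = gens if common is None else (common & gens)
    for tr in traces:
        for s in tr.partition_samples:
            if s.generation in (common or set()):
                by_gen.setdefault(s.generation, []).append(s.partition)
    rows = []
    for gen in sorted(by_gen):
        f = co_module_frequencies(by_gen[gen], shared_genes, nonshared_genes, generation=gen)
        rows.append((gen, f.p_shared_shared, f.p_nonshared_nonshared, f.p_shared_nonshared))
    return pd.DataFrame(rows, columns=["generation", "p_ss", "p_nn", "p_sn"])


def module_count_series(traces: Sequence[EvolutionTrace]) -> pd.DataFrame:
    """Mean number of modules in the best networks, per sampled generation."""
    if not traces:
        raise ValueError("need at least one trace")
    by_gen: Dict[int, List[int]] = {}
    for tr in traces:
        if not tr.partition_samples:
            raise ValueError("traces must carry partition samples")
        for s in tr.partition_samples:
            by_gen.setdefault(s.generation, []).append(s.n_modules)
    n_pop = len(traces)
    rows = [
        (gen, float(np.mean(vals)))
        for gen, vals in sorted(by_gen.items())
        if len(vals) == n_pop  # only generations sampled in every population
    ]
    return pd.DataFrame(rows, columns=["generation", "mean_n_modules"])


# ---------------------------------------------------------------------------
# Normalized modularity with a degree-sequence null cache
# ---------------------------------------------------------------------------


class NullStatsCache:
    """Memo of (sorted degree sequence) -> (null mean Q, null max Q)."""

    def __init__(self, n_null: int = 1000, rng: Optional[np.random.Generator] = None):
        self.n_null = n_null
        self.rng = np.random.default_rng(rng)
        self._stats: Dict[Tuple[int, ...], Tuple[float, float]] = {}

    def stats_for(self, graph) -> Tuple[float, float]:
        key = tuple(sorted(d for _, d in graph.degree()))
        if key not in self._stats:
            mean, mx, _ = null_q_statistics(graph, n_null=self.n_null, rng=self.rng)
            self._stats[key] = (mean, mx)
        return self._stats[key]


def qm_of_network(
    network: GeneNetwork, cache: Optional[NullStatsCache] = None,
    n_null: int = 1000, rng: Optional[np.random.Generator] = None,
) -> ModularityResult:
    """Normalized modularity of a genotype's undirected projection."""
    graph = project_to_graph(network)
    if cache is not None:
        return normalized_modularity(graph, n_null=cache.n_null, null_stats=cache.stats_for(graph))
    return normalized_modularity(graph, n_null=n_null, rng=rng)


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Replicated-run configuration shared by the experiment drivers."""

    regime: SelectionRegime
    n_populations: int
    seed: int
    evo_params: EvolutionParams = field(default_factory=EvolutionParams)
    fit_params: FitnessParams = field(default_factory=FitnessParams)
    sample_interval: Optional[int] = 25
    n_null: int = 1000
    #: phase-end Qm is averaged over this many best-network snapshots taken
    #: ``endpoint_spacing`` generations apart (ending at the phase boundary);
    #: 1 = single endpoint.  Averaging suppresses the generation-to-generation
    #: drift noise of single-snapshot modularity.
    endpoint_window: int = 1
    endpoint_spacing: int = 100

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ValueError("replicated experiments need >= 2 populations")
        lengths = {t.shape[0] for ph in self.regime.phases for t in ph.targets}
        if lengths and lengths != {self.evo_params.n_genes}:
            raise ValueError("target pattern lengths must all equal n_genes")


def _population_seed(seed: int, pop_index: int, *extra: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=[seed, pop_index, *extra])


def run_replicates(config: ExperimentConfig) -> List[EvolutionTrace]:
    """Independent replicate populations, seeded by population index so
    results do not depend on execution order."""
    return [
        evolve(
            config.regime,
            config.evo_params,
            config.fit_params,
            seed=_population_seed(config.seed, i),
            sample_interval=config.sample_interval,
        )
        for i in range(config.n_populations)
    ]


@dataclass
class SpecializationResult:
    traces: List[EvolutionTrace]
    qm: pd.DataFrame  # one row per population, one Qm column per phase end
    phase_ends: List[int]
    tests: List[PairedTestResult]  # consecutive phase-end comparisons

    def endpoint_test(self) -> PairedTestResult:
        """First-vs-last phase-end comparison."""
        first = self.qm[f"qm_gen{self.phase_ends[0]}"]
        last = self.qm[f"qm_gen{self.phase_ends[-1]}"]
        return paired_signed_rank(first, last)


def run_specialization_experiment(
    config: ExperimentConfig, null_cache: Optional[NullStatsCache] = None
) -> SpecializationResult:
    """Replicated run with best-network Qm at every phase boundary and
    paired signed-rank tests of Qm increase between consecutive boundaries.

    Handles the controls (single phase, neutral phases, arbitrary pattern
    sets) through the regime alone.
    """
    if null_cache is None:
        null_cache = NullStatsCache(n_null=config.n_null, rng=np.random.default_rng(config.seed))
    traces = run_replicates(config)
    ends = np.cumsum([ph.n_generations for ph in config.regime.phases]).tolist()
    cols: Dict[str, List[float]] = {f"qm_gen{g}": [] for g in ends}
    for tr in traces:
        for g in ends:
            window = [
                g - k * config.endpoint_spacing
                for k in range(config.endpoint_window)
                if g - k * config.endpoint_spacing >= 0
            ]
            vals = [
                qm_of_network(tr.best_network(gen), cache=null_cache).q_normalized
                for gen in window
            ]
            cols[f"qm_gen{g}"].append(float(np.mean(vals)))
    qm = pd.DataFrame(cols)
    qm.insert(0, "population", np.arange(config.n_populations))
    tests = [
        paired_signed_rank(qm[f"qm_gen{a}"], qm[f"qm_gen{b}"])
        for a, b in zip(ends[:-1], ends[1:])
    ]
    return SpecializationResult(traces=traces, qm=qm, phase_ends=ends, tests=tests)


@dataclass
class CooptionResult:
    """Matched-pair outcome of the co-option experiment."""

    fitness: pd.DataFrame  # per pair/arm/generation best and mean fitness
    summary: pd.DataFrame  # per pair: fitness at the evaluation generation
    n_pairs: int
    onset_generation: int
    eval_generation: int

    def wins(self, column: str = "best_fitness") -> int:
        """Pairs in which the co-option arm beats the random-pattern arm."""
        piv = self.summary.pivot(index="pair", columns="arm", values=column)
        return int((piv["cooption"] > piv["random"]).sum())


def run_cooption_experiment(
    pre_phases: List[Phase],
    cooption_target: np.ndarray,
    n_pairs: int,
    seed: int,
    post_generations: int,
    evo_params: Optional[EvolutionParams] = None,
    fit_params: Optional[FitnessParams] = None,
    eval_generation: Optional[int] = None,
    random_target_override: Optional[np.ndarray] = None,
) -> CooptionResult:
    """Matched-pair co-option experiment.

    Each pair shares one pre-phase history (selection for the ``pre_phases``
    pattern set, typically I+II+III), after which the population is copied
    into two arms evolving with identical random streams: one adds the
    module-recombining ``cooption_target`` (pattern IV) to the selected set,
    the control adds a uniformly random pattern.  Reported are per-arm best
    and mean fitness over the ``post_generations`` after onset, plus a
    summary at ``eval_generation`` generations past onset (default: the
    final generation).  Forcing ``random_target_override`` equal to the
    co-option target yields bit-identical arms, a harness self-check.
    """
    evo_params = evo_params or EvolutionParams()
    fit_params = fit_params or FitnessParams()
    if eval_generation is None:
        eval_generation = post_generations
    if not (1 <= eval_generation <= post_generations):
        raise ValueError("eval_generation must lie in [1, post_generations]")
    pre_targets = pre_phases[-1].targets
    if not pre_targets:
        raise ValueError("the final pre-phase must select at least one pattern")
    onset = sum(ph.n_generations for ph in pre_phases)

    rows = []
    for pair in range(n_pairs):
        pre_seed = _population_seed(seed, pair, 0)
        _tr, pop = evolve(
            SelectionRegime(list(pre_phases)),
            evo_params,
            fit_params,
            seed=pre_seed,
            sample_interval=None,
            return_population=True,
        )
        rng_ctrl = np.random.default_rng(_population_seed(seed, pair, 1))
        if random_target_override is not None:
            ctrl_target = random_target_override
        else:
            ctrl_target = random_pattern(evo_params.n_genes, rng_ctrl)
        for arm, fourth in (("cooption", cooption_target), ("random", ctrl_target)):
            post_regime = SelectionRegime(
                [Phase(post_generations, list(pre_targets) + [fourth])]
            )
            arm_seed = _population_seed(seed, pair, 2)  # same stream for both arms
            tr = evolve(
                post_regime,
                evo_params,
                fit_params,
                seed=arm_seed,
                sample_interval=None,
                initial_population=pop,
            )
            for g in range(1, post_generations + 1):
                rows.append(
                    (pair, arm, g, float(tr.max_fitness[g]), float(tr.mean_fitness[g]))
                )
    fitness = pd.DataFrame(
        rows, columns=["pair", "arm", "post_generation", "best_fitness", "mean_fitness"]
    )
    summary = (
        fitness[fitness.post_generation == eval_generation]
        .drop(columns="post_generation")
        .reset_index(drop=True)
    )
    return CooptionResult(
        fitness=fitness,
        summary=summary,
        n_pairs=n_pairs,
        onset_generation=onset,
        eval_generation=eval_generation,
    )
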