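"""Founders, the gain/loss mutation operator, selection, generation loop."""

import numpy as np
import pytest

from grnmod.core import GeneNetwork
from grnmod.evolution import (
    EvolutionParams,
    Phase,
    SelectionRegime,
    evolve,
    founder_network,
    loss_probability,
    mutate_gene,
    mutate_network,
    next_generation,
)
from grnmod.fitness import FitnessParams
from grnmod.fixtures import fig_pair_patterns


class TestFounder:
    def test_exact_edge_count(self, rng):
        net = founder_network(EvolutionParams(), rng)
        assert net.n_interactions == 20
        assert net.n_genes == 10

    def test_sign_balance(self):
        rng = np.random.default_rng(0)
        signs = []
        for _ in range(200):
            w = founder_network(EvolutionParams(), rng).interactions
            signs.extend(w[w != 0].tolist())
        frac_positive = np.mean(np.array(signs) > 0)
        assert frac_positive == pytest.approx(0.5, abs=0.03)

    def test_seed_reproducibility(self):
        a = founder_network(EvolutionParams(), np.random.default_rng(5))
        b = founder_network(EvolutionParams(), np.random.default_rng(5))
        assert a == b

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError, match="founder_edges"):
            EvolutionParams(n_genes=4, founder_edges=17)


class TestMutationOperator:
    def test_loss_probability_boundary_values(self):
        assert loss_probability(0, 10) == 0.0
        assert loss_probability(10, 10) == 1.0
        assert loss_probability(2, 10) == pytest.approx(0.5)  # gain/loss balance

    def test_empty_row_always_gains(self, rng):
        net = GeneNetwork(np.zeros((6, 6)))
        for _ in range(20):
            out = mutate_gene(net, 2, rng)
            row = out.interactions[2]
            assert np.count_nonzero(row) == 1
            assert np.abs(row).sum() == 1

    def test_full_row_always_loses(self, rng):
        w = np.ones((5, 5))
        for _ in range(20):
            out = mutate_gene(GeneNetwork(w), 0, rng)
            assert np.count_nonzero(out.interactions[0]) == 4

    def test_exactly_one_cell_changes(self, rng):
        net = founder_network(EvolutionParams(), rng)
        for gene in range(10):
            out = mutate_gene(net, gene, rng)
            diff = out.interactions != net.interactions
            assert diff.sum() == 1
            assert diff[gene].sum() == 1  # only the mutated gene's row
            delta = np.count_nonzero(out.interactions[gene]) - np.count_nonzero(
                net.interactions[gene]
            )
            assert delta in (-1, 1)

    def test_gain_then_loss_restores_genotype(self):
        # a gain followed by deletion of the same cell is the identity
        w = np.zeros((4, 4), dtype=np.int8)
        net = GeneNetwork(w)
        gained = mutate_gene(net, 1, np.random.default_rng(0))  # r=0: must gain
        cell = np.flatnonzero(gained.interactions[1])[0]
        reverted = gained.interactions.copy()
        reverted[1, cell] = 0
        assert GeneNetwork(reverted) == net

    def test_out_of_range_gene(self, rng):
        with pytest.raises(IndexError):
            mutate_gene(GeneNetwork(np.zeros((3, 3))), 3, rng)


class TestMutateNetwork:
    def test_mu_zero_is_identity(self, rng):
        net = founder_network(EvolutionParams(), rng)
        assert mutate_network(net, 0.0, rng) == net

    def test_mu_one_changes_every_row_once(self, rng):
        net = founder_network(EvolutionParams(), rng)
        out = mutate_network(net, 1.0, rng)
        diff = out.interactions != net.interactions
        assert (diff.sum(axis=1) == 1).all()

    def test_expected_number_of_mutated_genes(self):
        rng = np.random.default_rng(8)
        net = founder_network(EvolutionParams(), rng)
        hits = []
        for _ in range(600):
            out = mutate_network(net, 0.05, rng)
            hits.append((out.interactions != net.interactions).any(axis=1).sum())
        assert np.mean(hits) == pytest.approx(0.5, abs=0.1)  # mu * N = 0.5


class TestNextGeneration:
    def test_sole_fit_parent_takes_over(self, rng):
        pop = [GeneNetwork(np.zeros((3, 3))) for _ in range(10)]
        pop[3] = GeneNetwork(np.eye(3))
        fits = [0.0] * 10
        fits[3] = 1.0
        out = next_generation(pop, fits, rng)
        assert len(out) == 10
        assert all(net == pop[3] for net in out)

    def test_equal_fitness_is_uniform(self):
        rng = np.random.default_rng(0)
        pop = [GeneNetwork(np.full((2, 2), 0)) for _ in range(4)]
        counts = np.zeros(4)
        for _ in range(500):
            parents = rng.choice(4, size=4, p=np.full(4, 0.25))
            counts[parents] += 1
        # chi-square against uniform parentage
        expected = counts.sum() / 4
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < 16.27  # 0.001 critical value, df=3

    def test_zero_total_fitness_survives(self, rng):
        pop = [GeneNetwork(np.zeros((2, 2))) for _ in range(5)]
        out = next_generation(pop, [0.0] * 5, rng)
        assert len(out) == 5

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            next_generation([GeneNetwork(np.zeros((2, 2)))], [1.0, 2.0], rng)


class TestEvolve:
    def test_zero_generation_regime_records_initial_population_only(self):
        I, _ = fig_pair_patterns()
        trace = evolve(
            SelectionRegime([Phase(0, [I])]),
            EvolutionParams(population_size=20),
            FitnessParams(n_trajectories=10),
            seed=1,
        )
        assert len(trace) == 1
        assert trace.generation[0] == 0

    def test_identical_seeds_identical_traces(self):
        I, II = fig_pair_patterns()
        regime = SelectionRegime([Phase(5, [I]), Phase(5, [I, II])])
        kwargs = dict(
            evo_params=EvolutionParams(population_size=30),
            fit_params=FitnessParams(n_trajectories=20),
        )
        a = evolve(regime, seed=99, **kwargs)
        b = evolve(regime, seed=99, **kwargs)
        assert np.array_equal(a.best_genotypes, b.best_genotypes)
        assert np.array_equal(a.max_fitness, b.max_fitness)

    def test_record_count_and_phases(self):
        I, II = fig_pair_patterns()
        regime = SelectionRegime([Phase(4, [I]), Phase(3, [I, II])])
        trace = evolve(
            regime,
            EvolutionParams(population_size=20),
            FitnessParams(n_trajectories=10),
            seed=2,
        )
        assert len(trace) == 8  # generations 0..7
        assert trace.phase_index.tolist() == [0] * 5 + [1] * 3

    def test_neutral_phase_has_nan_fitness(self):
        trace = evolve(
            SelectionRegime([Phase(3, [])]),
            EvolutionParams(population_size=15),
            FitnessParams(n_trajectories=10),
            seed=3,
        )
        assert np.isnan(trace.max_fitness).all()

    def test_selection_response(self):
        # best fitness after 200 generations should beat generation 0 in
        # nearly every population
        I, _ = fig_pair_patterns()
        regime = SelectionRegime([Phase(200, [I])])
        wins = 0
        for s in range(5):
            trace = evolve(
                regime,
                EvolutionParams(),
                FitnessParams(n_trajectories=50),
                seed=np.random.SeedSequence([17, s]),
                sample_interval=None,
            )
            wins += trace.max_fitness[-1] > trace.max_fitness[0]
        assert wins >= 4

    def test_partition_samples_on_schedule(self):
        I, _ = fig_pair_patterns()
        trace = evolve(
            SelectionRegime([Phase(10, [I])]),
            EvolutionParams(population_size=20),
            FitnessParams(n_trajectories=10),
            seed=4,
            sample_interval=5,
        )
        gens = [s.generation for s in trace.partition_samples]
        assert set(gens) >= {0, 5, 10}
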