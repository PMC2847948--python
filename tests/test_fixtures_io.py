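"""Pattern generators, oracle graphs and plain-text serialization."""

import numpy as np
import pytest
from scipy.stats import binom, chisquare

from grnmod import io as gio
from grnmod.core import GeneNetwork, hamming_distance, pattern_to_bits
from grnmod.fixtures import (
    canonical_quartet,
    cooption_quartet,
    fig_pair_patterns,
    make_pattern_pair,
    oracle_graphs,
    random_oracle_graphs,
    random_pattern_pair,
    triple_patterns,
)
from grnmod.modularity import Partition, exhaustive_best_partition
from conftest import random_network


class TestPatternPairs:
    @pytest.mark.parametrize("k", [1, 3, 5, 7, 10])
    def test_exact_hamming_distance(self, k):
        a, b = make_pattern_pair(10, k)
        assert hamming_distance(a, b) == k
        # differing genes form the contiguous tail block
        assert (a[: 10 - k] == b[: 10 - k]).all()

    def test_random_placement(self, rng):
        a, b = make_pattern_pair(10, 4, rng=rng, placement="random")
        assert hamming_distance(a, b) == 4

    def test_degenerate_k_rejected(self):
        with pytest.raises(ValueError):
            make_pattern_pair(10, 0)
        with pytest.raises(ValueError):
            make_pattern_pair(10, 11)

    def test_canonical_pair_shares_first_half(self):
        I, II = fig_pair_patterns()
        assert (I[:5] == II[:5]).all()
        assert (I[5:] == -II[5:]).all()


class TestRandomPairs:
    def test_minimum_difference_respected(self, rng):
        for _ in range(200):
            a, b = random_pattern_pair(10, 2, rng)
            assert hamming_distance(a, b) >= 2

    def test_seeded_reproducibility(self):
        a1 = random_pattern_pair(10, 2, np.random.default_rng(4))
        a2 = random_pattern_pair(10, 2, np.random.default_rng(4))
        assert (a1[0] == a2[0]).all() and (a1[1] == a2[1]).all()

    def test_distance_distribution_is_truncated_binomial(self):
        # accepted pairs follow C(10,k) 0.5^10 renormalized over k >= 2
        rng = np.random.default_rng(10)
        ks = np.array([
            hamming_distance(*random_pattern_pair(10, 2, rng)) for _ in range(4000)
        ])
        pmf = binom.pmf(np.arange(11), 10, 0.5)
        pmf[:2] = 0.0
        pmf /= pmf.sum()
        # merge sparse tail bins (k<=3 and k>=8) for a stable chi-square
        edges = [(0, 3), (4, 4), (5, 5), (6, 6), (7, 10)]
        obs = [np.sum((ks >= lo) & (ks <= hi)) for lo, hi in edges]
        exp = [pmf[lo : hi + 1].sum() * len(ks) for lo, hi in edges]
        assert chisquare(obs, exp).pvalue > 1e-3


class TestQuartets:
    def test_random_quartet_block_structure(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            I, II, III, IV = cooption_quartet(10, rng)
            assert (IV[:5] == III[:5]).all()  # A-block copied from III
            assert (IV[5:] == II[5:]).all()  # B-block copied from II
            for other in (I, II, III):
                assert hamming_distance(IV, other) > 0
            # each block shows exactly two distinct states across I, II, III
            for sl in (slice(0, 5), slice(5, 10)):
                states = {pattern_to_bits(p[sl]) for p in (I, II, III)}
                assert len(states) == 2

    def test_canonical_quartet_is_near_balanced(self):
        # alternating block states keep every pattern within one gene of an
        # even active/inactive split (no all-active / all-inactive extremes)
        for p in canonical_quartet():
            assert abs(int(p.sum())) <= 2

    def test_odd_gene_count_rejected(self):
        with pytest.raises(ValueError):
            cooption_quartet(9, np.random.default_rng(0))


class TestTriple:
    def test_concerted_group_structure(self):
        I, II, III = triple_patterns()
        # phase-2 structure: genes 0-4 vs 5-9 is NOT the split here; instead
        # the changing group across I/II is {0,1,2,5,6}
        changing = {g for g in range(10) if I[g] != II[g]}
        assert changing == {0, 1, 2, 5, 6}
        # genes 5 and 6 anti-concerted in every pattern
        for p in (I, II, III):
            assert p[5] == -p[6]
        # genes 0 and 6 concerted across I, II only
        assert (I[0], II[0]) == (I[6], II[6])
        assert III[0] != III[6]
        # genes 0 and 8 part ways as soon as II is selected
        assert I[0] == I[8] and II[0] != II[8]
        # III differs from II at exactly the anti-concerted pair, splitting
        # the phase-2 changing group {0,1,2,5,6} into {0,1,2} and {5,6}
        assert {g for g in range(10) if II[g] != III[g]} == {5, 6}
        assert {g for g in range(10) if I[g] != III[g]} == {0, 1, 2}


class TestOracleGraphs:
    def test_named_fixture_optima_match_exhaustive(self):
        expected = {"two_k3": 0.5, "two_k4": 0.5, "k5": 0.0}
        graphs = oracle_graphs()
        for name, g in graphs.items():
            q = exhaustive_best_partition(g).q
            if name in expected:
                assert q == pytest.approx(expected[name])
        # bridged cliques split at the bridge
        res = exhaustive_best_partition(graphs["bridged_k5"])
        assert res.partition.labels.tolist() == [0] * 5 + [1] * 5

    def test_random_graph_set_is_deterministic(self):
        a = random_oracle_graphs(n_graphs=10)
        b = random_oracle_graphs(n_graphs=10)
        assert [n for n, _ in a] == [n for n, _ in b]
        assert all(sorted(g1.edges()) == sorted(g2.edges()) for (_, g1), (_, g2) in zip(a, b))
        assert all(g.number_of_edges() >= 2 for _, g in a)
        assert all(8 <= g.number_of_nodes() <= 10 for _, g in a)


class TestNetworkIO:
    def test_matrix_round_trip(self, tmp_path, rng):
        net = random_network(rng)
        path = tmp_path / "net.txt"
        gio.write_network(net, path, dialect="matrix")
        assert gio.read_network(path) == net

    def test_edge_list_round_trip(self, tmp_path, rng):
        net = random_network(rng)
        path = tmp_path / "net.edges"
        gio.write_network(net, path, dialect="edges")
        assert gio.read_network(path) == net

    def test_dialects_agree(self, tmp_path, rng):
        net = random_network(rng)
        gio.write_network(net, tmp_path / "a", dialect="matrix")
        gio.write_network(net, tmp_path / "b", dialect="edges")
        assert gio.read_network(tmp_path / "a") == gio.read_network(tmp_path / "b")

    def test_out_of_range_entry_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("# grnmod matrix\n0 2\n0 0\n")
        with pytest.raises(gio.NetworkParseError, match="line 2"):
            gio.read_network(p)

    def test_bad_edge_sign_rejected(self, tmp_path):
        p = tmp_path / "bad.edges"
        p.write_text("# grnmod edges n=3\n0\t1\t2\n")
        with pytest.raises(gio.NetworkParseError, match="sign"):
            gio.read_network(p)

    def test_headerless_square_table_sniffs_as_matrix(self, tmp_path):
        p = tmp_path / "plain.txt"
        p.write_text("0 1 0\n-1 0 0\n0 0 1\n")
        net = gio.read_network(p)
        assert net.n_genes == 3 and net.interactions[1, 0] == -1


class TestPatternAndPartitionIO:
    def test_pattern_file_round_trip(self, tmp_path):
        pats = dict(zip("I II III".split(), triple_patterns()))
        path = tmp_path / "patterns.txt"
        gio.write_patterns(pats, path)
        back = gio.read_patterns(path)
        assert list(back) == ["I", "II", "III"]
        assert all((back[k] == pats[k]).all() for k in pats)

    def test_partition_tsv_round_trip(self, tmp_path):
        part = Partition(np.array([0, 0, 1, 2, 1]))
        path = tmp_path / "partition.tsv"
        gio.write_partition(part, path)
        assert gio.read_partition(path).labels.tolist() == part.labels.tolist()
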