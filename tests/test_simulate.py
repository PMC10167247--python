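"""Unit and property tests for the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chisquare

from nfatevo import phylo, simulate, stats


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

class TestSpeciesTree:
    def test_two_leaves_ultrametric(self):
        sim = simulate.simulate_species_tree(2, 1.0, seed=7)
        sim.tree.calc_node_root_distances()
        d = [lf.root_distance for lf in sim.tree.leaf_node_iter()]
        assert len(d) == 2
        assert abs(d[0] - d[1]) < 1e-9

    def test_same_seed_same_newick(self):
        a = simulate.simulate_species_tree(10, 1.0, seed=42)
        b = simulate.simulate_species_tree(10, 1.0, seed=42)
        assert a.newick == b.newick
        c = simulate.simulate_species_tree(10, 1.0, seed=43)
        assert a.newick != c.newick

    def test_binary_internal_node_count(self):
        sim = simulate.simulate_species_tree(50, 1.0, seed=1)
        assert len(sim.tree.internal_nodes()) == 49
        assert len(sim.tree.leaf_nodes()) == 50

    def test_ultrametric_all_leaves(self):
        sim = simulate.simulate_species_tree(20, 2.0, seed=5)
        sim.tree.calc_node_root_distances()
        d = [lf.root_distance for lf in sim.tree.leaf_node_iter()]
        assert max(d) - min(d) < 1e-9

    def test_divergence_times_cover_all_pairs(self):
        sim = simulate.simulate_species_tree(6, 1.0, seed=2)
        assert len(sim.divergence_times) == 6 * 5 // 2
        assert all(t > 0 for t in sim.divergence_times.values())

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate.simulate_species_tree(1, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate.simulate_species_tree(5, 0.0, seed=0)


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

def _expected_duplications(tree, rate):
    """Closed-form expected event count of a pure-birth copy process:
    sum over edges of exp(rate*s) * (exp(rate*L) - 1), s = depth of edge top."""

    def walk(node, s):
        total = 0.0
        for child in node.child_nodes():
            L = child.edge.length
            total += math.exp(rate * s) * (math.exp(rate * L) - 1.0)
            total += walk(child, s + L)
        return total

    return walk(tree.seed_node, 0.0)


class TestGeneFamily:
    def test_no_events_matches_species_tree(self, species_tree):
        gf = simulate.simulate_gene_family(species_tree, 0.0, 0.0, seed=5)
        assert gf.true_duplication_nodes == set()
        assert len(gf.gene_tree.leaf_nodes()) == 8
        # one gene per species, topology congruent with the species tree
        relabeled = phylo.read_newick(gf.newick.replace("|g1", ""))
        assert phylo.rf_distance(relabeled, species_tree.tree) == 0

    def test_same_seed_same_tree_and_truth(self, species_tree):
        a = simulate.simulate_gene_family(species_tree, 0.4, 0.1, seed=9)
        b = simulate.simulate_gene_family(species_tree, 0.4, 0.1, seed=9)
        assert a.newick == b.newick
        assert a.true_duplication_nodes == b.true_duplication_nodes

    def test_mean_duplications_match_analytic_expectation(self, species_tree):
        rate = 0.5
        counts = [
            len(simulate.simulate_gene_family(species_tree, rate, 0.0, seed=5000 + i
                                              ).true_duplication_nodes)
            for i in range(300)
        ]
        expected = _expected_duplications(species_tree.tree, rate)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 1e-12

    def test_loss_free_leaf_count_identity(self, species_tree):
        """leaves = species leaves + sum over events of species leaves below."""
        below = {}
        for node in species_tree.tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            below[label] = sum(1 for _ in node.leaf_iter())
        for i in range(30):
            gf = simulate.simulate_gene_family(species_tree, 0.5, 0.0, seed=2000 + i)
            expected = 8 + sum(below[sp] for sp in gf.events.values())
            assert len(gf.gene_tree.leaf_nodes()) == expected

    def test_total_extinction_raises(self, species_tree):
        with pytest.raises(simulate.SimulationFailure):
            simulate.simulate_gene_family(
                species_tree, 0.0, 500.0, seed=1, max_retries=3
            )

    def test_negative_rate_rejected(self, species_tree):
        with pytest.raises(ValueError):
            simulate.simulate_gene_family(species_tree, -0.1, 0.0, seed=1)


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------

class TestCodonPair:
    def test_zero_divergence_identical(self):
        sim = simulate.simulate_codon_pair(0.5, 0.0, 2.0, 50, seed=3)
        assert sim.seq_a == sim.seq_b

    def test_omega_zero_no_nonsynonymous_differences(self):
        from nfatevo.selection import AMINO

        for seed in range(5):
            sim = simulate.simulate_codon_pair(0.0, 1.0, 2.0, 300, seed=seed)
            for k in range(0, len(sim.seq_a), 3):
                ca, cb = sim.seq_a[k : k + 3], sim.seq_b[k : k + 3]
                assert AMINO[ca] == AMINO[cb]

    def test_determinism(self):
        a = simulate.simulate_codon_pair(1.0, 0.4, 2.0, 100, seed=11)
        b = simulate.simulate_codon_pair(1.0, 0.4, 2.0, 100, seed=11)
        assert (a.seq_a, a.seq_b) == (b.seq_a, b.seq_b)

    def test_neutral_nonsyn_fraction_matches_rate_matrix(self):
        """Among single-nucleotide codon differences at small t, the
        nonsynonymous share approximates the rate-matrix flux share,
        computed here independently from the generator matrix."""
        kappa = 2.0
        Q = simulate.gy94_rate_matrix(1.0, kappa)
        codons = simulate.SENSE_CODONS
        non = tot = 0.0
        for i, a in enumerate(codons):
            for j, b in enumerate(codons):
                if i == j:
                    continue
                tot += Q[i, j]
                if simulate._AA[a] != simulate._AA[b]:
                    non += Q[i, j]
        expected = non / tot
        sim = simulate.simulate_codon_pair(1.0, 0.1, kappa, 100_000, seed=12)
        ns = s = 0
        for k in range(0, len(sim.seq_a), 3):
            ca, cb = sim.seq_a[k : k + 3], sim.seq_b[k : k + 3]
            if ca != cb and sum(x != y for x, y in zip(ca, cb)) == 1:
                if simulate._AA[ca] != simulate._AA[cb]:
                    ns += 1
                else:
                    s += 1
        assert abs(ns / (ns + s) - expected) < 0.02

    def test_codon_frequencies_uniform(self):
        sim = simulate.simulate_codon_pair(1.0, 0.8, 2.0, 50_000, seed=11)
        from collections import Counter

        counts = Counter(sim.seq_a[k : k + 3] for k in range(0, len(sim.seq_a), 3))
        observed = [counts[c] for c in simulate.SENSE_CODONS]
        assert chisquare(observed).pvalue > 0.01

    def test_rate_matrix_rows_sum_to_zero(self):
        Q = simulate.gy94_rate_matrix(0.7, 3.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        # normalized: one expected substitution per unit time at uniform freqs
        assert np.isclose(-np.mean(np.diag(Q)), 1.0)

    def test_probability_matrix_consistency(self):
        # P(t) from the generator matches an independent matrix exponential
        Q = simulate.gy94_rate_matrix(2.0, 2.0)
        P = expm(Q * 0.3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= -1e-12


# ---------------------------------------------------------------------------
# gene orders
# ---------------------------------------------------------------------------

class TestGeneOrders:
    def test_no_ops_no_breakpoints(self):
        sim = simulate.simulate_gene_orders(6, {"s": []})
        assert sim.planted_breakpoints["s"] == set()
        assert sim.target_orders["s"] == sim.reference_order

    def test_single_inversion_example(self):
        sim = simulate.simulate_gene_orders(5, {"s": [("inversion", 2, 3)]})
        assert sim.target_orders["s"] == ["g1", "g2", "g4", "g3", "g5"]
        assert sim.planted_breakpoints["s"] == {
            frozenset(("g2", "g3")),
            frozenset(("g4", "g5")),
        }

    def test_full_reversal_plants_nothing(self):
        sim = simulate.simulate_gene_orders(7, {"s": [("inversion", 0, 6)]})
        assert sim.target_orders["s"] == list(reversed(sim.reference_order))
        assert sim.planted_breakpoints["s"] == set()

    def test_translocation_and_swap(self):
        sim = simulate.simulate_gene_orders(
            6, {"a": [("translocation", 1, 2, 3)], "b": [("swap", 0, 5)]}
        )
        assert sorted(sim.target_orders["a"]) == sorted(sim.reference_order)
        assert sim.target_orders["b"][0] == "g6"
        for sp in ("a", "b"):
            got = simulate.adjacency_set(sim.reference_order) - simulate.adjacency_set(
                sim.target_orders[sp]
            )
            assert got == sim.planted_breakpoints[sp]

    def test_bad_indices_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_gene_orders(5, {"s": [("inversion", 3, 9)]})
        with pytest.raises(ValueError):
            simulate.simulate_gene_orders(3, {})

    def test_random_inversions_are_interior_and_disjoint(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ops = simulate.random_inversion_ops(20, 3, rng)
            cuts = sorted(x for _, i, j in ops for x in (i, j))
            assert cuts[0] >= 1 and cuts[-1] <= 18
            assert all(b - a >= 1 for a, b in zip(cuts, cuts[1:]))


# ---------------------------------------------------------------------------
# ratio pairs
# ---------------------------------------------------------------------------

class TestRatioDataset:
    def test_noise_free_is_exactly_linear(self):
        df = simulate.simulate_ratio_dataset(50, 2.0, 1.0, 0.0, seed=8)
        res = stats.pearson_r2(df["x"], df["y"])
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(2.0)

    def test_null_slope_r2_small(self):
        low = sum(
            stats.pearson_r2(*simulate.simulate_ratio_dataset(
                10_000, 0.0, 0.0, 1.0, seed=s
            ).T.values).r2 < 0.01
            for s in range(20)
        )
        assert low >= 19  # >= 95% of seeds

    def test_determinism_and_validation(self):
        a = simulate.simulate_ratio_dataset(10, 1.0, 0.0, 0.5, seed=2)
        b = simulate.simulate_ratio_dataset(10, 1.0, 0.0, 0.5, seed=2)
        assert a.equals(b)
        with pytest.raises(ValueError):
            simulate.simulate_ratio_dataset(2, 1.0, 0.0, 0.5, seed=2)
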