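"""Tests for tree I/O, duplication labeling, RF distance, Fitch and ILD."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfatevo import phylo, simulate


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

class TestNewick:
    def test_two_leaf_tree(self):
        t = phylo.read_newick("(A,B);")
        labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        assert labels == ["A", "B"]

    def test_roundtrip_preserves_lengths(self):
        text = "((A:1.0,B:1.0):1.0,C:2.0);"
        once = phylo.write_newick(phylo.read_newick(text))
        twice = phylo.write_newick(phylo.read_newick(once))
        assert once == twice
        t = phylo.read_newick(once)
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_malformed_raises(self):
        with pytest.raises(phylo.NewickParseError):
            phylo.read_newick("((A,B;")

    def test_quoted_labels_and_multifurcation(self):
        t = phylo.read_newick("('sp one',B,C,D);")
        assert len(t.leaf_nodes()) == 4
        assert len(t.seed_node.child_nodes()) == 4


# ---------------------------------------------------------------------------
# species-overlap labeling + duplication ratio
# ---------------------------------------------------------------------------

def brute_force_duplications(tree, species_of):
    """Independent oracle: explicit species-set intersection at every node,
    collecting leaf sets by full subtree walks (quadratic, no shared state)."""
    dups = []
    for node in tree.preorder_internal_node_iter():
        child_species = [
            {species_of(lf.taxon.label) for lf in c.leaf_iter()}
            for c in node.child_nodes()
        ]
        overlap = any(
            a & b for a, b in itertools.combinations(child_species, 2)
        )
        dups.append((frozenset(lf.taxon.label for lf in node.leaf_iter()), overlap))
    return dups


class TestSpeciesOverlap:
    def test_single_visible_duplication(self):
        t = phylo.read_newick("(((A|g1,B|g2),(A|g3,B|g4)),C|g5);")
        ann = phylo.species_overlap_labels(t)
        assert ann.duplication_count == 1
        assert ann.n_internal == 4
        assert phylo.duplication_ratio(ann) == 0.25

    def test_congruent_tree_no_duplications(self):
        t = phylo.read_newick("(((A|g1,B|g1),C|g1),D|g1);")
        ann = phylo.species_overlap_labels(t)
        assert ann.duplication_count == 0
        assert phylo.duplication_ratio(ann) == 0.0

    def test_pectinate_paralog_family_all_duplications(self):
        t = phylo.read_newick("(A|g1,(A|g2,(A|g3,A|g4)));")
        ann = phylo.species_overlap_labels(t)
        assert phylo.duplication_ratio(ann) == 1.0

    def test_species_map_and_unmapped_leaf_error(self):
        t = phylo.read_newick("((x,y),z);")
        smap = {"x": "A", "y": "A", "z": "B"}
        ann = phylo.species_overlap_labels(t, species_map=smap)
        assert ann.duplication_count == 1
        with pytest.raises(ValueError, match="z"):
            phylo.species_overlap_labels(t, species_map={"x": "A", "y": "A"})

    def test_multifurcation_any_overlapping_pair(self):
        t = phylo.read_newick("(A|g1,B|g1,B|g2);")
        ann = phylo.species_overlap_labels(t)
        assert ann.duplication_count == 1

    def test_node_total_modes_and_undefined(self):
        t = phylo.read_newick("(((A|g1,B|g2),(A|g3,B|g4)),C|g5);")
        ann = phylo.species_overlap_labels(t)
        assert phylo.duplication_ratio(ann, "internal") == 0.25
        assert phylo.duplication_ratio(ann, "all") == 1 / 9
        leaf_only = phylo.read_newick("A|g1;")
        with pytest.raises(phylo.UndefinedRatioError):
            phylo.duplication_ratio(phylo.species_overlap_labels(leaf_only))

    def test_matches_bruteforce_on_random_gene_trees(self, species_tree):
        for i in range(25):
            gf = simulate.simulate_gene_family(species_tree, 0.5, 0.2, seed=300 + i)
            ann = phylo.species_overlap_labels(gf.gene_tree)
            oracle = brute_force_duplications(
                gf.gene_tree, lambda lab: lab.split("|", 1)[0]
            )
            assert ann.duplication_count == sum(flag for _, flag in oracle)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_ratio_invariant_under_rescaling_and_child_order(self, seed):
        sp = simulate.simulate_species_tree(5, 1.0, seed=17)
        gf = simulate.simulate_gene_family(sp, 0.6, 0.0, seed=seed % 997)
        base = phylo.duplication_ratio(phylo.species_overlap_labels(gf.gene_tree))
        t2 = phylo.read_newick(gf.newick)
        for node in t2.preorder_node_iter():
            if node.edge.length:
                node.edge.length *= 13.7
            node._child_nodes.reverse()
        assert phylo.duplication_ratio(phylo.species_overlap_labels(t2)) == base


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

class TestRfDistance:
    def test_identical_zero(self):
        t1 = phylo.read_newick("((A,B),(C,D));")
        t2 = phylo.read_newick("((B,A),(D,C));")
        assert phylo.rf_distance(t1, t2) == 0

    def test_conflicting_quartet(self):
        t1 = phylo.read_newick("((A,B),(C,D));")
        t2 = phylo.read_newick("((A,C),(B,D));")
        assert phylo.rf_distance(t1, t2) == 2

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(0)
        for i in range(5):
            a = simulate.simulate_species_tree(7, 1.0, seed=int(rng.integers(1e6)))
            b = simulate.simulate_species_tree(7, 1.0, seed=int(rng.integers(1e6)))
            # rename b's leaves to match a's label set
            d = phylo.rf_distance(a.tree, b.tree)
            assert d == phylo.rf_distance(b.tree, a.tree)
            assert 0 <= d <= 2 * (7 - 3)

    def test_leaf_mismatch_raises(self):
        t1 = phylo.read_newick("((A,B),C);")
        t2 = phylo.read_newick("((A,B),D);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            phylo.rf_distance(t1, t2)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def exhaustive_fitch(tree, site):
    """Oracle: minimize state changes over every internal-node assignment."""
    internals = list(tree.postorder_internal_node_iter())
    leaves = list(tree.leaf_node_iter())
    alphabet = sorted(set(site.values()))
    best = None
    for assign in itertools.product(alphabet, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assign)}
        for lf in leaves:
            state[id(lf)] = site[lf.taxon.label]
        changes = sum(
            state[id(n)] != state[id(c)]
            for n in internals
            for c in n.child_nodes()
        )
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    def test_constant_site_zero(self):
        t = phylo.read_newick("((a,b),(c,d));")
        assert phylo.fitch_length(t, dict.fromkeys("abcd", "R")) == 0

    @pytest.mark.parametrize(
        "states,expected",
        [({"a": "R", "b": "R", "c": "Y", "d": "Y"}, 1),
         ({"a": "R", "b": "Y", "c": "R", "d": "Y"}, 2)],
    )
    def test_quartet_examples(self, states, expected):
        t = phylo.read_newick("((a,b),(c,d));")
        assert phylo.fitch_length(t, states) == expected

    def test_matches_exhaustive_minimization(self):
        rng = np.random.default_rng(6)
        for i in range(8):
            sim = simulate.simulate_species_tree(int(rng.integers(4, 9)), 1.0,
                                                 seed=50 + i)
            leaves = [lf.taxon.label for lf in sim.tree.leaf_node_iter()]
            site = {lf: "ACGT"[rng.integers(4)] for lf in leaves}
            assert phylo.fitch_length(sim.tree, site) == exhaustive_fitch(sim.tree, site)

    def test_missing_state_raises(self):
        t = phylo.read_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="no state"):
            phylo.fitch_length(t, {"a": "R", "b": "R", "c": "Y"})


# ---------------------------------------------------------------------------
# ILD test
# ---------------------------------------------------------------------------

def _simulate_matrix(tree, n_chars, rate, rng):
    """Binary characters evolved by symmetric change along the topology."""
    out = {lf.taxon.label: [] for lf in tree.leaf_node_iter()}
    for _ in range(n_chars):
        states = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                states[id(node)] = rng.integers(2)
            else:
                flip = rng.random() < rate
                states[id(node)] = states[id(node.parent_node)] ^ flip
            if node.is_leaf():
                out[node.taxon.label].append("RY"[states[id(node)]])
    return {k: "".join(v) for k, v in out.items()}


class TestIld:
    def test_homoplasy_free_statistic_zero(self):
        tree = phylo.read_newick("((a,b),(c,d));")
        part = {"a": "RR", "b": "RR", "c": "YY", "d": "YY"}
        res = phylo.ild_test(part, part, phylo.fixed_tree_search(tree), n_perm=99, seed=0)
        assert res.statistic == 0
        assert res.p_value == 1.0

    def test_exhaustive_search_matches_fixed_on_true_tree(self):
        # on data perfectly congruent with one topology, the exhaustive
        # minimum equals that topology's Fitch length
        tree = phylo.read_newick("((a,b),(c,d));")
        matrix = {"a": "RRRY", "b": "RRRY", "c": "YYRR", "d": "YYRY"}
        fixed = phylo.fixed_tree_search(tree)
        assert phylo.exhaustive_parsimony_search(matrix) <= fixed(matrix)

    def test_topology_enumeration_counts(self):
        for n, expect in ((4, 3), (5, 15), (6, 105)):
            labels = [f"t{i}" for i in range(n)]
            assert sum(1 for _ in phylo._all_binary_topologies(labels)) == expect

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(1)
        tree = simulate.simulate_species_tree(6, 1.0, seed=9).tree
        a = _simulate_matrix(tree, 12, 0.2, rng)
        b = _simulate_matrix(tree, 12, 0.2, rng)
        search = phylo.exhaustive_tree_search(sorted(a))
        r1 = phylo.ild_test(a, b, search, n_perm=99, seed=5)
        r2 = phylo.ild_test(a, b, search, n_perm=99, seed=5)
        assert r1 == r2

    def test_taxa_mismatch_raises(self):
        with pytest.raises(ValueError, match="same taxa"):
            phylo.ild_test({"a": "R"}, {"b": "R"}, None, n_perm=99)

    def test_null_calibration_congruent_partitions(self):
        """Partitions simulated on one topology are rarely called incongruent."""
        rng = np.random.default_rng(7)
        tree = simulate.simulate_species_tree(5, 1.0, seed=21).tree
        search = phylo.exhaustive_tree_search(
            [lf.taxon.label for lf in tree.leaf_node_iter()]
        )
        rejections = 0
        n_runs = 40
        for i in range(n_runs):
            a = _simulate_matrix(tree, 15, 0.25, rng)
            b = _simulate_matrix(tree, 15, 0.25, rng)
            res = phylo.ild_test(a, b, search, n_perm=99, seed=100 + i)
            rejections += res.p_value < 0.05
        assert rejections / n_runs <= 0.2
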