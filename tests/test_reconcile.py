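import numpy as np
import pytest

from _oracles import (min_mapping_cost, min_mapping_cost_literal,
                      rooting_costs_via_dendropy)
from conftest import random_gene_tree, random_rooted_tree
from gtpipe.families import TaxonMap
from gtpipe.reconcile import (count_events, lca_map, optimal_rooting,
                              reconciliation_cost, root_by_outgroup)
from gtpipe.treekit import TreeError, parse_newick


@pytest.fixture
def abc_species():
    return parse_newick("((A,B),C);")


@pytest.fixture
def abc_taxa():
    return TaxonMap({"a1": "A", "a2": "A", "b1": "B", "c1": "C"})


class TestLcaMap:
    def test_congruent_trees_map_onto_matching_nodes(self, abc_species, abc_taxa):
        g = parse_newick("((a1,b1),c1);")
        mapping = lca_map(g, abc_species, abc_taxa)
        by_leafset = {frozenset(k.leaf_labels()): frozenset(v.leaf_labels())
                      for k, v in mapping.items() if not k.is_leaf}
        assert by_leafset[frozenset({"a1", "b1"})] == frozenset({"A", "B"})
        assert by_leafset[frozenset({"a1", "b1", "c1"})] == frozenset({"A", "B", "C"})

    def test_paralogous_node_maps_to_child_lca(self, abc_species, abc_taxa):
        g = parse_newick("((a1,(a2,b1)),c1);")
        mapping = lca_map(g, abc_species, abc_taxa)
        by_leafset = {frozenset(k.leaf_labels()): frozenset(v.leaf_labels())
                      for k, v in mapping.items() if not k.is_leaf}
        assert by_leafset[frozenset({"a2", "b1"})] == frozenset({"A", "B"})
        assert by_leafset[frozenset({"a1", "a2", "b1"})] == frozenset({"A", "B"})

    def test_single_species_subtree_maps_to_that_leaf(self, abc_species, abc_taxa):
        g = parse_newick("(a1,a2);")
        mapping = lca_map(g, abc_species, abc_taxa)
        assert all(v.leaf_labels() == {"A"} for v in mapping.values())

    def test_unknown_taxon_is_an_error(self, abc_species):
        g = parse_newick("(x1,c1);")
        taxa = TaxonMap({"x1": "X", "c1": "C"})
        with pytest.raises(TreeError, match="X"):
            lca_map(g, abc_species, taxa)

    def test_nonbinary_gene_tree_rejected(self, abc_species, abc_taxa):
        g = parse_newick("(a1,a2,b1,c1);", rooted=True)
        with pytest.raises(TreeError, match="binary"):
            lca_map(g, abc_species, abc_taxa)


class TestCountEvents:
    @pytest.mark.parametrize("newick,D,L", [
        ("((a1,b1),c1);", 0, 0),        # congruent
        ("((a1,(a2,b1)),c1);", 1, 1),   # one duplication, one loss
        ("(a1,c1);", 0, 1),             # B-lineage loss on the root path
        ("(a1,a2);", 1, 0),             # in-paralog cherry
    ])
    def test_hand_checked_counts(self, abc_species, abc_taxa, newick, D, L):
        res = count_events(parse_newick(newick), abc_species, abc_taxa)
        assert (res.duplications, res.losses) == (D, L)

    def test_event_labels_match_counts(self, abc_species, abc_taxa):
        res = count_events(parse_newick("((a1,(a2,b1)),c1);"),
                           abc_species, abc_taxa)
        dups = [n for n, e in res.events.items() if e == "duplication"]
        assert len(dups) == res.duplications == 1
        assert dups[0].leaf_labels() == {"a1", "a2", "b1"}

    def test_cost_models(self, abc_species, abc_taxa):
        g = parse_newick("((a1,(a2,b1)),c1);")
        assert reconciliation_cost(g, abc_species, abc_taxa, "dup") == 1
        assert reconciliation_cost(g, abc_species, abc_taxa, "duploss") == 2
        with pytest.raises(ValueError):
            reconciliation_cost(g, abc_species, abc_taxa, "bogus")

    def test_cost_ignores_branch_lengths(self, abc_species, abc_taxa):
        rng = np.random.default_rng(0)
        g = parse_newick("((a1,(a2,b1)),c1);")
        base = reconciliation_cost(g, abc_species, abc_taxa, "duploss")
        for _ in range(20):
            g2 = g.copy()
            for node in g2.postorder():
                if node is not g2.root:
                    node.length = float(rng.uniform(0.01, 5))
            assert reconciliation_cost(g2, abc_species, abc_taxa,
                                       "duploss") == base


class TestLcaMapOptimality:
    """The LCA map attains the minimum D+L (and minimum D) over all
    valid mappings, checked against exhaustive enumeration."""

    def test_dp_oracle_matches_literal_enumeration_on_tiny_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sp = random_rooted_tree(["S0", "S1", "S2"], rng)
            gt, taxa = random_gene_tree(["S0", "S1", "S2"], 4, rng)
            assert (min_mapping_cost(gt, sp, taxa)
                    == min_mapping_cost_literal(gt, sp, taxa))

    def test_lca_map_minimises_dup_plus_loss(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_sp = int(rng.integers(3, 7))
            sp = random_rooted_tree([f"S{i}" for i in range(n_sp)], rng)
            gt, taxa = random_gene_tree([f"S{i}" for i in range(n_sp)],
                                        int(rng.integers(3, 11)), rng)
            res = count_events(gt, sp, taxa)
            assert res.duplications + res.losses == min_mapping_cost(gt, sp, taxa)
            assert res.duplications == min_mapping_cost(
                gt, sp, taxa, dup_weight=1, loss_weight=0)


class TestStructuralProperties:
    def test_adding_in_paralog_cherry_adds_one_dup_no_loss(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_sp = int(rng.integers(3, 7))
            labels = [f"S{i}" for i in range(n_sp)]
            sp = random_rooted_tree(labels, rng)
            gt, taxa = random_gene_tree(labels, int(rng.integers(3, 9)), rng)
            before = count_events(gt, sp, taxa)
            g2 = gt.copy()
            leaves = g2.leaves()
            victim = leaves[int(rng.integers(len(leaves)))]
            taxon = taxa.taxon_of(victim.label)
            twin_a, twin_b = f"{victim.label}x", f"{victim.label}y"
            victim.children = []
            from gtpipe.treekit import Node
            victim.add_child(Node(twin_a))
            victim.add_child(Node(twin_b))
            victim.label = None
            taxa2 = TaxonMap({**taxa.seq_to_taxon,
                              twin_a: taxon, twin_b: taxon})
            after = count_events(g2, sp, taxa2)
            assert after.duplications == before.duplications + 1
            assert after.losses == before.losses

    def test_pruning_a_leaf_never_increases_duplications(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n_sp = int(rng.integers(3, 7))
            labels = [f"S{i}" for i in range(n_sp)]
            sp = random_rooted_tree(labels, rng)
            gt, taxa = random_gene_tree(labels, int(rng.integers(4, 10)), rng)
            before = count_events(gt, sp, taxa)
            g2 = gt.copy()
            victim = sorted(g2.leaf_labels)[int(rng.integers(g2.n_leaves))]
            g2.prune_leaves({victim})
            if g2.n_leaves < 2:
                continue
            after = count_events(g2, sp, taxa)
            assert after.duplications <= before.duplications


class TestOptimalRooting:
    def test_true_rooting_recovers_zero_cost(self, abc_species, abc_taxa):
        g = parse_newick("((a1,b1),c1);")
        best, cost = optimal_rooting(g, abc_species, abc_taxa, "duploss")
        assert cost == 0
        assert best.canonical_newick() == g.canonical_newick()

    def test_minimum_beats_every_fixed_rooting(self, abc_species):
        rng = np.random.default_rng(9)
        from gtpipe.treekit import enumerate_rootings
        for _ in range(30):
            gt, taxa = random_gene_tree(["A", "B", "C"],
                                        int(rng.integers(3, 8)), rng)
            _, best = optimal_rooting(gt, abc_species, taxa, "dup")
            for rooted in enumerate_rootings(gt):
                assert best <= reconciliation_cost(rooted, abc_species,
                                                   taxa, "dup")

    def test_agrees_with_independent_dendropy_enumeration(self, abc_species):
        rng = np.random.default_rng(10)
        for _ in range(20):
            gt, taxa = random_gene_tree(["A", "B", "C"],
                                        int(rng.integers(3, 8)), rng)
            oracle = rooting_costs_via_dendropy(
                gt, lambda t: reconciliation_cost(t, abc_species, taxa, "dup"))
            _, best = optimal_rooting(gt, abc_species, taxa, "dup")
            assert best == min(oracle)
            assert len(oracle) == 2 * gt.n_leaves - 3


class TestOutgroupRooting:
    def test_priority_order(self, simple_taxa):
        # nematode (A) outranks arthropod (B)
        t = parse_newick("(c1,d1,(a1,b1));")
        rooted = root_by_outgroup(t, simple_taxa)
        sides = {frozenset(c.leaf_labels()) for c in rooted.root.children}
        assert frozenset({"a1"}) in sides

    def test_arthropod_used_when_no_nematode(self, simple_taxa):
        t = parse_newick("(c1,d1,(b1,b2));")
        rooted = root_by_outgroup(t, simple_taxa)
        sides = {frozenset(c.leaf_labels()) for c in rooted.root.children}
        assert frozenset({"b1", "b2"}) in sides  # clade rooting

    def test_no_outgroup_leaves_tree_unrooted(self, simple_taxa):
        t = parse_newick("((c1,d1),(c2,d2));")
        taxa = TaxonMap({"c1": "C", "c2": "C", "d1": "D", "d2": "D"},
                        {"C": {"Annelida"}, "D": {"Platyhelminthes"}})
        out = root_by_outgroup(t, taxa)
        assert not out.rooted
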