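import numpy as np
import pytest

from conftest import random_rooted_tree
from gtpipe.families import TaxonMap
from gtpipe.gtp_search import (GtpProblem, bootstrap_gtp, brute_force_gtp,
                               enumerate_rooted_topologies, heuristic_search,
                               spr_neighbors, starred_newick, total_cost)
from gtpipe.synthetic_data import simulate_gene_family, simulate_species_tree, taxon_map_for
from gtpipe.treekit import TreeError, parse_newick


def congruent_problem(n_copies=5, **kw):
    """Gene trees all congruent with one species tree, single copy."""
    sp = parse_newick("(((T1,T2),T3),T4);")
    taxa = TaxonMap({f"T{i}|1": f"T{i}" for i in range(1, 5)})
    gt = parse_newick("(((T1|1,T2|1),T3|1),T4|1);")
    return sp, GtpProblem([gt.copy() for _ in range(n_copies)], taxa, **kw)


def simulated_problem(n_taxa, n_families, seed, lam=0.3, mu=0.3,
                      sampling=0.8, **kw):
    sp = simulate_species_tree(n_taxa, seed=seed)
    fams = []
    s = seed * 10_000
    while len(fams) < n_families:
        fam = simulate_gene_family(sp, lam, mu, sampling, seed=s)
        s += 1
        if fam.gene_tree is not None and not fam.too_small:
            fams.append(fam)
    taxa = taxon_map_for(fams, sp)
    return sp, GtpProblem([f.gene_tree for f in fams], taxa,
                          rooting="fixed", **kw)


class TestTotalCost:
    def test_congruent_trees_cost_zero(self):
        sp, problem = congruent_problem()
        total, breakdown = total_cost(sp, problem)
        assert total == 0 and breakdown == [0] * 5

    def test_additivity_under_tree_duplication(self):
        sp, problem = simulated_problem(5, 8, seed=2)
        total, breakdown = total_cost(sp, problem)
        doubled = GtpProblem(list(problem.gene_trees)
                             + [problem.gene_trees[0]],
                             problem.taxa, rooting="fixed")
        total2, _ = total_cost(sp, doubled)
        assert total2 == total + breakdown[0]

    def test_breakdown_sums_to_total_and_order_invariant(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            sp, problem = simulated_problem(5, 6, seed=seed + 1)
            total, breakdown = total_cost(sp, problem)
            assert total == sum(breakdown)
            perm = list(rng.permutation(len(problem.gene_trees)))
            shuffled = GtpProblem([problem.gene_trees[i] for i in perm],
                                  problem.taxa, rooting="fixed")
            assert total_cost(sp, shuffled)[0] == total

    def test_missing_taxon_named_in_error(self):
        _, problem = congruent_problem()
        small = parse_newick("((T1,T2),T3);")
        with pytest.raises(TreeError, match="T4"):
            total_cost(small, problem)


class TestBruteForce:
    def test_topology_counts(self):
        assert len(list(enumerate_rooted_topologies("ABC"))) == 3
        assert len(list(enumerate_rooted_topologies("ABCD"))) == 15
        assert len(list(enumerate_rooted_topologies("ABCDE"))) == 105

    def test_congruent_input_has_unique_zero_argmin(self):
        sp, problem = congruent_problem()
        result = brute_force_gtp(problem)
        assert result.best_cost == 0
        assert len(result.all_optima) == 1
        assert result.best_tree.canonical_newick() == sp.canonical_newick()

    def test_taxa_limit_enforced(self):
        _, problem = simulated_problem(9, 2, seed=1, sampling=1.0)
        with pytest.raises(ValueError, match="heuristic"):
            brute_force_gtp(problem, taxa_limit=8)


class TestSprNeighbors:
    def test_neighbors_are_distinct_valid_trees(self):
        rng = np.random.default_rng(1)
        t = random_rooted_tree([f"T{i}" for i in range(6)], rng)
        neigh = spr_neighbors(t)
        forms = {n.canonical_newick() for n in neigh}
        assert len(forms) == len(neigh)
        assert t.canonical_newick() not in forms
        assert all(n.leaf_labels == t.leaf_labels and n.is_binary()
                   for n in neigh)

    def test_neighborhood_reaches_every_5_taxon_topology(self):
        """SPR connects the rooted-topology space: repeated neighborhood
        expansion from one tree must enumerate all 105 topologies."""
        start = parse_newick("((((A,B),C),D),E);")
        seen = {start.canonical_newick()}
        frontier = [start]
        while frontier:
            nxt = []
            for t in frontier:
                for n in spr_neighbors(t):
                    key = n.canonical_newick()
                    if key not in seen:
                        seen.add(key)
                        nxt.append(n)
            frontier = nxt
        assert len(seen) == 105


class TestHeuristic:
    def test_recovers_generating_tree_from_congruent_families(self):
        sp, _ = congruent_problem()
        taxa = TaxonMap({f"T{i}|1": f"T{i}" for i in range(1, 5)})
        gt = parse_newick("(((T1|1,T2|1),T3|1),T4|1);")
        problem = GtpProblem([gt.copy() for _ in range(50)], taxa,
                             restarts=3, seed=1)
        result = heuristic_search(problem)
        assert result.best_cost == 0
        assert result.best_tree.canonical_newick() == sp.canonical_newick()

    def test_same_seed_same_result_and_trace(self):
        _, p1 = simulated_problem(6, 10, seed=4, restarts=3)
        _, p2 = simulated_problem(6, 10, seed=4, restarts=3)
        r1, r2 = heuristic_search(p1), heuristic_search(p2)
        assert r1.best_tree.canonical_newick() == r2.best_tree.canonical_newick()
        assert r1.trace == r2.trace

    def test_trace_costs_non_increasing_within_restart(self):
        _, problem = simulated_problem(6, 12, seed=5, restarts=3)
        result = heuristic_search(problem)
        by_restart = {}
        for restart, rnd, cost in result.trace:
            by_restart.setdefault(restart, []).append(cost)
        for costs in by_restart.values():
            assert costs == sorted(costs, reverse=True)

    def test_never_beats_brute_force_and_usually_matches(self):
        matches = 0
        for seed in range(20):
            _, problem = simulated_problem(5, 10, seed=seed + 20,
                                           restarts=5)
            bf = brute_force_gtp(problem)
            h = heuristic_search(problem)
            assert h.best_cost >= bf.best_cost
            if h.best_cost == bf.best_cost:
                matches += 1
        assert matches >= 18

    def test_zero_cost_family_never_moves_a_unique_argmin(self):
        sp, problem = congruent_problem(n_copies=30)
        taxa = problem.taxa
        extra = parse_newick("(((T1|1,T2|1),T3|1),T4|1);")
        bigger = GtpProblem(list(problem.gene_trees) + [extra], taxa,
                            restarts=3, seed=0)
        result = heuristic_search(bigger)
        assert result.best_tree.canonical_newick() == sp.canonical_newick()


class TestBootstrapGtp:
    def test_identical_bootstrap_trees_star_every_clade(self):
        sp, problem = simulated_problem(5, 10, seed=7, restarts=3)
        result = heuristic_search(problem)
        boots = [[t.copy(), t.copy()] for t in problem.gene_trees]
        bres, stars = bootstrap_gtp(boots, problem, result.best_tree)
        assert (bres.best_tree.canonical_newick()
                == result.best_tree.canonical_newick())
        assert all(stars.values())

    def test_single_differing_clade_unstarred(self):
        ref = parse_newick("((((A,B),C),D),E);")
        boot = parse_newick("((((A,C),B),D),E);")  # one NNI away
        ref_clades = set(ref.clades())
        boot_clades = set(boot.clades())
        stars = {c: c in boot_clades for c in ref_clades}
        unstarred = {c for c, v in stars.items() if not v}
        assert unstarred == ref_clades - boot_clades
        nwk = starred_newick(ref, stars)
        assert nwk.count("*") == len(ref_clades) - len(unstarred)

    def test_empty_pool_rejected(self):
        _, problem = congruent_problem()
        with pytest.raises(ValueError, match="empty"):
            bootstrap_gtp([[]], problem, problem.gene_trees[0])
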