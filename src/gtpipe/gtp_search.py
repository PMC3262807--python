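"""Gene tree parsimony: species-tree inference minimising total
reconciliation cost over a set of gene trees.

The search optimises the sum over gene families of the duplication (or
duplication + loss) cost.  An exhaustive enumerator over all rooted
binary topologies serves as the oracle for small taxon sets; the working
method is hill-climbing over the rooted-SPR neighbourhood from random
taxon-addition starting trees, with restarts.  Unrooted gene trees can
contribute their optimal-rooting cost, mirroring the behaviour of
reconciliation software that re-roots each gene tree while scoring a
candidate species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .families import TaxonMap
from .reconcile import (CompiledGeneTree, CostModel, SpeciesIndex,
                        _check_model, enumerate_rootings)
from .treekit import Node, PhyloTree, TreeError

__all__ = [
    "GtpProblem",
    "GtpResult",
    "total_cost",
    "brute_force_gtp",
    "heuristic_search",
    "bootstrap_gtp",
    "enumerate_rooted_topologies",
    "spr_neighbors",
]

ROOTING_POLICIES = ("fixed", "optimize-all", "optimize-unrooted-only")


@dataclass
class GtpProblem:
    gene_trees: Sequence[PhyloTree]
    taxa: TaxonMap
    model: CostModel = "dup"
    rooting: str = "optimize-unrooted-only"
    restarts: int = 10
    seed: int = 0
    max_rounds: int = 50

    def __post_init__(self):
        if not self.gene_trees:
            raise ValueError("at least one gene tree is required")
        _check_model(self.model)
        if self.rooting not in ROOTING_POLICIES:
            raise ValueError(f"unknown rooting policy {self.rooting!r}")

    def taxon_set(self) -> set[str]:
        out: set[str] = set()
        for t in self.gene_trees:
            out |= {self.taxa.taxon_of(l) for l in t.leaf_labels}
        return out


@dataclass
class GtpResult:
    best_tree: PhyloTree
    best_cost: int
    breakdown: list[int]
    trace: list[tuple[int, int, int]] = field(default_factory=list)  # (restart, round, cost)
    all_optima: list[PhyloTree] | None = None
    converged: bool = True


class _ScoredProblem:
    """Gene trees compiled once; candidate species trees scored many times.

    Under the optimising policies an unrooted (or every) gene tree is
    pre-compiled in all 2n-3 rootings and contributes the cheapest one
    per candidate species tree.
    """

    def __init__(self, problem: GtpProblem):
        self.model = problem.model
        self.units: list[list[CompiledGeneTree]] = []
        for gt in problem.gene_trees:
            optimize = (problem.rooting == "optimize-all"
                        or (problem.rooting == "optimize-unrooted-only"
                            and not gt.rooted))
            if optimize:
                variants = [CompiledGeneTree(r, problem.taxa)
                            for r in enumerate_rootings(gt)]
            else:
                if not gt.rooted:
                    raise TreeError(
                        "unrooted gene tree under rooting policy 'fixed'")
                variants = [CompiledGeneTree(gt, problem.taxa)]
            self.units.append(variants)

    def breakdown(self, sp: SpeciesIndex) -> list[int]:
        dup_only = self.model == "dup"
        out = []
        for variants in self.units:
            best = None
            for cg in variants:
                D, L, _ = cg.reconcile(sp)
                c = D if dup_only else D + L
                if best is None or c < best:
                    best = c
            out.append(best)
        return out

    def score(self, species_tree: PhyloTree) -> int:
        return sum(self.breakdown(SpeciesIndex(species_tree)))


def total_cost(species_tree: PhyloTree, problem: GtpProblem,
               ) -> tuple[int, list[int]]:
    """Total reconciliation cost of all gene trees against one species
    tree, plus the per-family breakdown."""
    missing = problem.taxon_set() - species_tree.leaf_labels
    if missing:
        raise TreeError(f"species tree lacks taxa: {sorted(missing)}")
    sp = SpeciesIndex(species_tree)
    bd = _ScoredProblem(problem).breakdown(sp)
    return sum(bd), bd


# -- topology enumeration ---------------------------------------------------


def _tree_from_shape(shape) -> PhyloTree:
    def build(s) -> Node:
        if isinstance(s, str):
            return Node(s)
        n = Node()
        n.add_child(build(s[0]))
        n.add_child(build(s[1]))
        return n

    return PhyloTree(build(shape), rooted=True)


def _all_shapes(labels: Sequence[str]):
    """All rooted binary topologies as nested tuples, by stepwise leaf
    addition to every edge (including above the root)."""
    shapes = [labels[0]]
    for label in labels[1:]:
        nxt = []
        for s in shapes:
            nxt.extend(_insert_everywhere(s, label))
        shapes = nxt
    return shapes


def _insert_everywhere(shape, label):
    yield (shape, label)  # new root above the old one
    if not isinstance(shape, str):
        left, right = shape
        for sub in _insert_everywhere(left, label):
            yield (sub, right)
        for sub in _insert_everywhere(right, label):
            yield (left, sub)


def enumerate_rooted_topologies(taxa: Iterable[str]) -> Iterable[PhyloTree]:
    """Every rooted binary topology on the taxon set ((2n-3)!! of them)."""
    labels = sorted(set(taxa))
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    for shape in _all_shapes(labels):
        yield _tree_from_shape(shape)


def brute_force_gtp(problem: GtpProblem, taxa_limit: int = 8) -> GtpResult:
    """Global optimum by exhaustive enumeration of rooted species-tree
    topologies; all argmin trees are kept (canonical order, first
    reported as best)."""
    taxa = sorted(problem.taxon_set())
    if len(taxa) > taxa_limit:
        raise ValueError(
            f"{len(taxa)} taxa exceed the exhaustive limit {taxa_limit}; "
            "use heuristic_search")
    scorer = _ScoredProblem(problem)
    best_cost = None
    optima: list[tuple[str, PhyloTree, list[int]]] = []
    for tree in enumerate_rooted_topologies(taxa):
        bd = scorer.breakdown(SpeciesIndex(tree))
        cost = sum(bd)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            optima = [(tree.canonical_newick(), tree, bd)]
        elif cost == best_cost:
            optima.append((tree.canonical_newick(), tree, bd))
    optima.sort(key=lambda t: t[0])
    _, best_tree, bd = optima[0]
    return GtpResult(best_tree, best_cost, bd,
                     all_optima=[t for _, t, _ in optima])


# -- SPR neighbourhood ------------------------------------------------------


def spr_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """Rooted SPR neighbourhood: every non-root subtree regrafted onto
    every edge outside it (including the edge above the root), original
    topology excluded.  Deterministic canonical order, deduplicated."""
    base = tree.canonical_newick()
    seen = {base}
    out = []
    nodes = list(tree.postorder())
    for prune_i, _ in enumerate(nodes):
        for graft_i, _ in enumerate(nodes):
            cand = _spr_move(tree, prune_i, graft_i)
            if cand is None:
                continue
            key = cand.canonical_newick()
            if key not in seen:
                seen.add(key)
                out.append(cand)
    out.sort(key=lambda t: t.canonical_newick())
    return out


def _spr_move(tree: PhyloTree, prune_i: int, graft_i: int) -> PhyloTree | None:
    t = tree.copy()
    nodes = list(t.postorder())
    prune = nodes[prune_i]
    graft = nodes[graft_i]
    if prune.parent is None:
        return None
    # graft target must not be inside the pruned subtree
    anc = graft
    while anc is not None:
        if anc is prune:
            return None
        anc = anc.parent
    parent = prune.parent
    if graft is parent:
        return None
    prune.detach()
    # collapse the degree-2 node left behind
    if parent.parent is None:
        sibling = parent.children[0]
        sibling.parent = None
        sibling.length = None
        t.root = sibling
        if graft is parent:
            return None
    else:
        gp = parent.parent
        sibling = parent.children[0]
        idx = gp.children.index(parent)
        sibling.parent = gp
        gp.children[idx] = sibling
        if graft is parent:
            graft = sibling
    if graft is t.root:
        new_root = Node()
        new_root.add_child(t.root)
        new_root.add_child(prune)
        t.root = new_root
    else:
        mid = Node()
        gparent = graft.parent
        idx = gparent.children.index(graft)
        graft.parent = mid
        mid.children.append(graft)
        mid.add_child(prune)
        mid.parent = gparent
        gparent.children[idx] = mid
    prune.length = None
    return PhyloTree(t.root, rooted=True)


# -- heuristic search -------------------------------------------------------


def _random_addition_tree(taxa: Sequence[str], rng: np.random.Generator,
                          ) -> PhyloTree:
    order = list(taxa)
    rng.shuffle(order)
    root = Node()
    root.add_child(Node(order[0]))
    root.add_child(Node(order[1]))
    tree = PhyloTree(root, rooted=True)
    for label in order[2:]:
        nodes = [n for n in tree.postorder() if n.parent is not None]
        target = nodes[int(rng.integers(len(nodes)))]
        mid = Node()
        parent = target.parent
        idx = parent.children.index(target)
        target.parent = mid
        mid.children.append(target)
        mid.add_child(Node(label))
        mid.parent = parent
        parent.children[idx] = mid
    return PhyloTree(tree.root, rooted=True)


def heuristic_search(problem: GtpProblem,
                     start_tree: PhyloTree | None = None) -> GtpResult:
    """SPR hill-climbing with random-addition restarts.

    Within a restart the current tree moves to the best strictly
    improving SPR neighbour (ties to the lexicographically smallest
    canonical Newick) until a local optimum or the round cap; the best
    local optimum across restarts is returned.  Deterministic for a
    fixed seed.
    """
    taxa = sorted(problem.taxon_set())
    if len(taxa) < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    scorer = _ScoredProblem(problem)
    rng = np.random.default_rng(problem.seed)
    best: tuple[int, str, PhyloTree] | None = None
    trace: list[tuple[int, int, int]] = []
    converged = True
    for restart in range(problem.restarts):
        if start_tree is not None and restart == 0:
            current = start_tree.copy()
        else:
            current = _random_addition_tree(taxa, rng)
        cost = scorer.score(current)
        trace.append((restart, 0, cost))
        for rnd in range(1, problem.max_rounds + 1):
            improved = None
            for cand in spr_neighbors(current):
                c = scorer.score(cand)
                if c < cost and (improved is None or c < improved[0]):
                    improved = (c, cand)
            if improved is None:
                break
            cost, current = improved
            trace.append((restart, rnd, cost))
        else:
            converged = False
        key = (cost, current.canonical_newick())
        if best is None or key < (best[0], best[1]):
            best = (cost, current.canonical_newick(), current)
    assert best is not None
    bd = scorer.breakdown(SpeciesIndex(best[2]))
    return GtpResult(best[2], best[0], bd, trace=trace, converged=converged)


# -- bootstrap GTP ----------------------------------------------------------


def bootstrap_gtp(bootstrap_sets: Sequence[Sequence[PhyloTree]],
                  problem: GtpProblem,
                  reference_tree: PhyloTree,
                  ) -> tuple[GtpResult, dict[frozenset[str], bool]]:
    """Pool every bootstrap gene tree into one problem, search, and mark
    which clades of the reference species tree recur in the bootstrap
    species tree (the star marks drawn on the main tree)."""
    pooled = [t for trees in bootstrap_sets for t in trees]
    if not pooled:
        raise ValueError("empty bootstrap tree pool")
    bp = GtpProblem(pooled, problem.taxa, model=problem.model,
                    rooting=problem.rooting, restarts=problem.restarts,
                    seed=problem.seed, max_rounds=problem.max_rounds)
    result = heuristic_search(bp)
    boot_clades = set(result.best_tree.clades())
    stars = {clade: clade in boot_clades
             for clade in reference_tree.clades()}
    return result, stars


def starred_newick(reference_tree: PhyloTree,
                   stars: dict[frozenset[str], bool]) -> str:
    """Reference tree with '*' internal labels on supported clades."""
    t = reference_tree.copy()
    for node in t.postorder():
        if node.is_leaf:
            continue
        if stars.get(frozenset(node.leaf_labels()), False):
            node.label = "*"
    return t.to_newick()
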