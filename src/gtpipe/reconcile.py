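"""Gene-tree/species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the most recent species-tree node whose
leaf set covers the species of its descendant genes.  An internal gene
node is a *duplication* when it maps to the same species node as one of
its children, otherwise a *speciation*.  Losses are read off the species
paths between a node's mapping and its children's mappings: a
duplication implies a loss for every edge skipped on either child path,
a speciation for every edge beyond the first.  The LCA map attains the
minimum duplication + loss total over all valid mappings, which makes
these counts the parsimony reconciliation cost.

Two cost models are exposed: ``dup`` (duplications only, the criterion
optimised by classic gene-tree-parsimony software) and ``duploss``
(duplications plus losses).

A compiled array representation (:class:`SpeciesIndex`,
:class:`CompiledGeneTree`) backs the species-tree search, where the same
gene trees are reconciled against thousands of candidate species trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .families import TaxonMap
from .treekit import Node, PhyloTree, TreeError, enumerate_rootings, unroot

__all__ = [
    "CostModel",
    "ReconciliationResult",
    "SpeciesIndex",
    "CompiledGeneTree",
    "lca_map",
    "count_events",
    "reconciliation_cost",
    "optimal_rooting",
    "root_by_outgroup",
]

COST_MODELS = ("dup", "duploss")
CostModel = str


def _check_model(model: CostModel) -> None:
    if model not in COST_MODELS:
        raise ValueError(f"unknown cost model {model!r}; expected one of {COST_MODELS}")


# -- compiled species tree --------------------------------------------------


class SpeciesIndex:
    """Array view of a rooted species tree: postorder node numbering,
    parent/depth arrays, and a dense LCA table."""

    def __init__(self, species_tree: PhyloTree):
        if not species_tree.rooted:
            raise TreeError("species tree must be rooted")
        self.tree = species_tree
        nodes = list(species_tree.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int32)
        self.depth = np.zeros(n, dtype=np.int32)
        for i, node in enumerate(nodes):
            if node.parent is not None:
                self.parent[i] = self.index[id(node.parent)]
        for node in species_tree.preorder():
            i = self.index[id(node)]
            p = self.parent[i]
            self.depth[i] = 0 if p < 0 else self.depth[p] + 1
        self.leaf_index = {nd.label: self.index[id(nd)]
                           for nd in nodes if nd.is_leaf}
        self.lca_table = self._build_lca_table(n)

    def _build_lca_table(self, n: int) -> np.ndarray:
        table = np.zeros((n, n), dtype=np.int32)
        parent, depth = self.parent, self.depth
        for i in range(n):
            for j in range(i, n):
                a, b = i, j
                while a != b:
                    if depth[a] >= depth[b]:
                        a = parent[a]
                    else:
                        b = parent[b]
                table[i, j] = table[j, i] = a
        return table

    def node_at(self, i: int) -> Node:
        return self.nodes[i]


class CompiledGeneTree:
    """Postorder array form of a rooted binary gene tree; leaf slots hold
    the taxon name so one compilation serves every candidate species tree."""

    __slots__ = ("taxa", "left", "right", "n_leaves", "n_nodes", "tree")

    def __init__(self, gene_tree: PhyloTree, taxa: TaxonMap):
        if not gene_tree.rooted:
            raise TreeError("gene tree must be rooted for reconciliation")
        nodes = list(gene_tree.postorder())
        idx = {id(n): i for i, n in enumerate(nodes)}
        self.tree = gene_tree
        self.n_nodes = len(nodes)
        self.n_leaves = 0
        self.taxa: list[str | None] = [None] * self.n_nodes
        self.left = np.full(self.n_nodes, -1, dtype=np.int32)
        self.right = np.full(self.n_nodes, -1, dtype=np.int32)
        for i, node in enumerate(nodes):
            if node.is_leaf:
                self.taxa[i] = taxa.taxon_of(node.label)
                self.n_leaves += 1
            else:
                if len(node.children) != 2:
                    raise TreeError("gene tree must be binary for reconciliation")
                self.left[i] = idx[id(node.children[0])]
                self.right[i] = idx[id(node.children[1])]

    def reconcile(self, sp: SpeciesIndex) -> tuple[int, int, np.ndarray]:
        """(duplications, losses, node→species mapping array)."""
        mapping = np.empty(self.n_nodes, dtype=np.int32)
        leaf_index = sp.leaf_index
        lca = sp.lca_table
        depth = sp.depth
        left, right, taxa = self.left, self.right, self.taxa
        D = 0
        L = 0
        for i in range(self.n_nodes):
            t = taxa[i]
            if t is not None:
                try:
                    mapping[i] = leaf_index[t]
                except KeyError:
                    raise TreeError(f"gene-tree taxon {t!r} is not a species-tree leaf")
                continue
            m1 = mapping[left[i]]
            m2 = mapping[right[i]]
            m = lca[m1, m2]
            mapping[i] = m
            d1 = depth[m1] - depth[m]
            d2 = depth[m2] - depth[m]
            if m == m1 or m == m2:
                D += 1
                L += d1 + d2
            else:
                L += d1 + d2 - 2
        return D, L, mapping


# -- public API -------------------------------------------------------------


@dataclass
class ReconciliationResult:
    mapping: dict  # gene Node -> species Node
    events: dict   # internal gene Node -> "duplication" | "speciation"
    duplications: int
    losses: int
    model: CostModel = "duploss"

    @property
    def cost(self) -> int:
        return self.duplications if self.model == "dup" else self.duplications + self.losses


def lca_map(gene_tree: PhyloTree, species_tree: PhyloTree,
            taxa: TaxonMap) -> dict:
    """The LCA mapping, gene node → species node, via one postorder pass."""
    return count_events(gene_tree, species_tree, taxa).mapping


def count_events(gene_tree: PhyloTree, species_tree: PhyloTree,
                 taxa: TaxonMap, model: CostModel = "duploss",
                 ) -> ReconciliationResult:
    """Reconcile one rooted binary gene tree against a rooted species
    tree; returns the mapping, per-node event labels, and counts."""
    _check_model(model)
    sp = SpeciesIndex(species_tree)
    cg = CompiledGeneTree(gene_tree, taxa)
    D, L, mapping_arr = cg.reconcile(sp)
    gnodes = list(gene_tree.postorder())
    mapping = {}
    events = {}
    for i, gnode in enumerate(gnodes):
        snode = sp.node_at(int(mapping_arr[i]))
        mapping[gnode] = snode
        if not gnode.is_leaf:
            child_maps = {int(mapping_arr[cg.left[i]]), int(mapping_arr[cg.right[i]])}
            events[gnode] = ("duplication" if int(mapping_arr[i]) in child_maps
                             else "speciation")
    return ReconciliationResult(mapping, events, D, L, model)


def reconciliation_cost(gene_tree: PhyloTree, species_tree: PhyloTree,
                        taxa: TaxonMap, model: CostModel = "dup") -> int:
    """D under ``dup``, D + L under ``duploss``; topology-only."""
    _check_model(model)
    sp = SpeciesIndex(species_tree)
    D, L, _ = CompiledGeneTree(gene_tree, taxa).reconcile(sp)
    return D if model == "dup" else D + L


def optimal_rooting(gene_tree: PhyloTree, species_tree: PhyloTree,
                    taxa: TaxonMap, model: CostModel = "dup",
                    sp: SpeciesIndex | None = None,
                    ) -> tuple[PhyloTree, int]:
    """Minimum reconciliation cost over every rooting of the gene tree's
    unrooted topology (one rooting per edge, 2n-3 for a binary tree).

    Ties break to the lexicographically smallest canonical Newick so the
    returned rooting is deterministic.
    """
    _check_model(model)
    if sp is None:
        sp = SpeciesIndex(species_tree)
    best: tuple[int, str, PhyloTree] | None = None
    for rooted in enumerate_rootings(gene_tree):
        D, L, _ = CompiledGeneTree(rooted, taxa).reconcile(sp)
        cost = D if model == "dup" else D + L
        key = (cost, rooted.canonical_newick())
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], rooted)
    assert best is not None
    return best[2], best[0]


def annotate_events(gene_tree: PhyloTree, result: ReconciliationResult) -> PhyloTree:
    """Copy of the gene tree with internal labels D/S from the event map."""
    t = gene_tree  # label in place on the caller's copy responsibility
    for node, ev in result.events.items():
        node.label = "D" if ev == "duplication" else "S"
    return t


# -- outgroup rooting -------------------------------------------------------


DEFAULT_ROOTING_PRIORITY = ("Nematoda", "Arthropoda")


def root_by_outgroup(gene_tree: PhyloTree, taxa: TaxonMap,
                     priority: Sequence[str] = DEFAULT_ROOTING_PRIORITY,
                     ) -> PhyloTree:
    """Root on the highest-priority outgroup present.

    The priority list is scanned in order; the first group with at least
    one leaf in the tree is used.  Several outgroup leaves root the tree
    on the edge separating them when they form a clade in some rooting,
    otherwise on the terminal edge of the first such leaf by id.  With no
    outgroup at all the tree is returned unrooted-flagged — a valid
    outcome, not an error.
    """
    leaves_by_group: dict[str, list[str]] = {g: [] for g in priority}
    for leaf in gene_tree.leaves():
        for g in taxa.seq_groups(leaf.label):
            if g in leaves_by_group:
                leaves_by_group[g].append(leaf.label)
    chosen: list[str] | None = None
    for g in priority:
        if leaves_by_group[g]:
            chosen = sorted(leaves_by_group[g])
            break
    if chosen is None:
        u = unroot(gene_tree)
        u.rooted = False
        return u
    if gene_tree.n_leaves < 3:
        return gene_tree.copy()
    outgroup = frozenset(chosen)
    rest = frozenset(gene_tree.leaf_labels) - outgroup
    for rooted in enumerate_rootings(gene_tree):
        sides = {frozenset(c.leaf_labels()) for c in rooted.root.children}
        if sides == {outgroup, rest}:
            return rooted
    # outgroup not a clade in any rooting: root on the first leaf's edge
    target = frozenset({chosen[0]})
    for rooted in enumerate_rootings(gene_tree):
        sides = {frozenset(c.leaf_labels()) for c in rooted.root.children}
        if target in sides:
            return rooted
    raise TreeError("no rooting isolates the outgroup leaf")  # pragma: no cover
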