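"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: event counting is
re-derived by dynamic programming (and, at tiny sizes, literal recursive
enumeration) over ALL valid gene-to-species mappings; rooting
enumeration goes through dendropy's re-rooting; quartet resolutions are
read by physically pruning dendropy trees to four leaves.
"""

from itertools import product

import dendropy

from gtpipe.families import TaxonMap
from gtpipe.treekit import PhyloTree, parse_newick

INF = 10 ** 9


def _species_arrays(species_tree: PhyloTree):
    nodes = list(species_tree.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = [idx[id(n.parent)] if n.parent is not None else -1 for n in nodes]
    depth = []
    for n in nodes:
        d = 0
        p = n
        while p.parent is not None:
            p = p.parent
            d += 1
        depth.append(d)
    leaf_of = {n.label: idx[id(n)] for n in nodes if n.is_leaf}
    anc_or_self = []
    for i in range(len(nodes)):
        chain = [i]
        while parent[chain[-1]] != -1:
            chain.append(parent[chain[-1]])
        anc_or_self.append(chain)
    return idx, parent, depth, leaf_of, anc_or_self


def _child_under(s, u, anc):
    """Index of s's child whose subtree holds u (u a strict descendant of
    s), else None."""
    chain = anc[u]
    if s not in chain or s == u:
        return None
    k = chain.index(s)
    return chain[k - 1]


def _local_cost(s, su, sv, depth, anc,
                dup_weight=1, loss_weight=1):
    """Cost contribution of one internal gene node mapped to s with
    children mapped to su, sv.

    The node is a speciation only when the two child lineages descend
    through distinct daughters of s (the event labels must stay
    consistent with the embedding); anything else is a duplication.
    """
    d1 = depth[su] - depth[s]
    d2 = depth[sv] - depth[s]
    cu = _child_under(s, su, anc)
    cv = _child_under(s, sv, anc)
    speciation = cu is not None and cv is not None and cu != cv
    if speciation:
        return loss_weight * (d1 + d2 - 2)
    return dup_weight + loss_weight * (d1 + d2)


def min_mapping_cost(gene_tree: PhyloTree, species_tree: PhyloTree,
                     taxa: TaxonMap, dup_weight=1, loss_weight=1) -> int:
    """Minimum of dup_weight*D + loss_weight*L over ALL valid mappings
    (leaves fixed to their species; mapping(parent) an ancestor-or-self
    of mapping(child)), by exact dynamic programming."""
    _, parent, depth, leaf_of, anc = _species_arrays(species_tree)
    n_s = len(depth)
    gnodes = list(gene_tree.postorder())
    cost = {}
    for g in gnodes:
        row = [INF] * n_s
        if g.is_leaf:
            row[leaf_of[taxa.taxon_of(g.label)]] = 0
        else:
            u, v = g.children
            cu, cv = cost[id(u)], cost[id(v)]
            for s in range(n_s):
                best = INF
                # children may map to any node whose ancestor-or-self is s
                for su in range(n_s):
                    if cu[su] >= INF or s not in anc[su]:
                        continue
                    for sv in range(n_s):
                        if cv[sv] >= INF or s not in anc[sv]:
                            continue
                        c = (cu[su] + cv[sv]
                             + _local_cost(s, su, sv, depth, anc,
                                           dup_weight, loss_weight))
                        if c < best:
                            best = c
                row[s] = best
        cost[id(g)] = row
    return min(cost[id(gnodes[-1])])


def min_mapping_cost_literal(gene_tree: PhyloTree, species_tree: PhyloTree,
                             taxa: TaxonMap) -> int:
    """Same minimum (D + L) by literal enumeration of every valid
    mapping; exponential — tiny instances only."""
    _, parent, depth, leaf_of, anc = _species_arrays(species_tree)
    gnodes = list(gene_tree.postorder())
    internal = [g for g in gnodes if not g.is_leaf]
    fixed = {id(g): leaf_of[taxa.taxon_of(g.label)]
             for g in gnodes if g.is_leaf}
    n_s = len(depth)
    best = INF
    for combo in product(range(n_s), repeat=len(internal)):
        mapping = dict(fixed)
        for g, s in zip(internal, combo):
            mapping[id(g)] = s
        ok = True
        total = 0
        for g in internal:
            s = mapping[id(g)]
            su, sv = (mapping[id(c)] for c in g.children)
            if s not in anc[su] or s not in anc[sv]:
                ok = False
                break
            total += _local_cost(s, su, sv, depth, anc)
        if ok and total < best:
            best = total
    return best


def rooting_costs_via_dendropy(gene_tree: PhyloTree, cost_fn) -> list[int]:
    """Costs of every rooting of the gene tree's unrooted topology,
    enumerated independently with dendropy edge re-rooting; ``cost_fn``
    maps a rooted PhyloTree to a cost."""
    nwk = gene_tree.to_newick(lengths=False)
    base = dendropy.Tree.get(data=nwk, schema="newick",
                             suppress_internal_node_taxa=True)
    base.is_rooted = False
    base.collapse_basal_bifurcation()
    n_edges = sum(1 for e in base.preorder_edge_iter()
                  if e.head_node is not base.seed_node)
    costs = []
    for k in range(n_edges):
        t = dendropy.Tree.get(data=base.as_string(schema="newick"),
                              schema="newick",
                              suppress_internal_node_taxa=True)
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        edges = [e for e in t.preorder_edge_iter()
                 if e.head_node is not t.seed_node]
        edge = edges[k]
        t.reroot_at_edge(edge)
        rooted = parse_newick(t.as_string(schema="newick").strip(),
                              rooted=True)
        costs.append(cost_fn(rooted))
    return costs


def quartet_pair_by_pruning(tree: PhyloTree, quartet: set[str]):
    """Which pair of the quartet groups together, found by pruning a
    dendropy copy of the tree down to the four leaves; None if
    unresolved."""
    dt = dendropy.Tree.get(data=tree.to_newick(lengths=False),
                           schema="newick",
                           suppress_internal_node_taxa=True)
    dt.retain_taxa_with_labels(sorted(quartet))
    dt.is_rooted = False
    dt.collapse_basal_bifurcation()
    dt.suppress_unifurcations()
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        labels = {l.taxon.label for l in node.leaf_iter()}
        if len(labels) == 2:
            return frozenset(labels)
    return None
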