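"""Rooted/unrooted phylogenetic trees, Newick I/O, and the primitives
(LCA, ancestor paths, re-rooting) that the reconciliation and search
modules build on.

Trees are stored as a parent/child linked structure rooted at an
arbitrary node; an explicit ``rooted`` flag distinguishes a genuinely
rooted tree (basal bifurcation) from an unrooted one stored
rooted-at-a-trifurcation.  Branch lengths are optional: operations that
need them raise rather than silently assuming zero.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import dendropy
from dendropy.dataio.newickreader import NewickReader as _NewickReader
from dendropy.utility import error as _dendropy_error

__all__ = [
    "Node",
    "PhyloTree",
    "NewickError",
    "TreeError",
    "parse_newick",
    "read_newick_file",
    "read_newick_list",
    "write_newick_file",
    "enumerate_rootings",
    "robinson_foulds",
    "leaf_label_report",
]


class TreeError(ValueError):
    """Structural misuse of a tree (wrong rootedness, unknown label, ...)."""


class NewickError(ValueError):
    """Malformed Newick input; message carries the offending position."""


class Node:
    """A tree node; ``length`` is the length of the edge to the parent."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> set[str]:
        return {n.label for n in self.leaves()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} nchild={len(self.children)}>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


class PhyloTree:
    """A phylogenetic tree with unique leaf labels.

    ``rooted`` records whether the basal node is a true root (two
    children) or the arbitrary anchor of an unrooted topology (three or
    more children).
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        labels = [n.label for n in self.root.postorder() if n.is_leaf]
        if any(lbl is None for lbl in labels):
            raise TreeError("every leaf must carry a label")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return PhyloTree(_copy(self.root), rooted=self.rooted)

    # -- basic accessors ------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> set[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise TreeError(f"leaf {label!r} not in tree")

    def is_binary(self) -> bool:
        """True if every internal node bifurcates (unrooted: basal node
        may trifurcate)."""
        for n in self.postorder():
            if n.is_leaf:
                continue
            if n is self.root:
                want = 2 if self.rooted else 3
                if len(n.children) != want:
                    return False
            elif len(n.children) != 2:
                return False
        return True

    # -- primitives -----------------------------------------------------

    def lca(self, labels: Iterable[str]) -> Node:
        """Deepest node whose leaf set contains all ``labels``.

        Only defined on rooted trees.
        """
        if not self.rooted:
            raise TreeError("LCA requires a rooted tree")
        labels = set(labels)
        if not labels:
            raise TreeError("LCA of an empty label set is undefined")
        unknown = labels - self.leaf_labels
        if unknown:
            raise TreeError(f"labels not in tree: {sorted(unknown)}")
        paths: list[list[Node]] = []
        for leaf in self.leaves():
            if leaf.label in labels:
                path = [leaf]
                while path[-1].parent is not None:
                    path.append(path[-1].parent)
                paths.append(path[::-1])
        lca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                lca = level[0]
            else:
                break
        assert lca is not None
        return lca

    def edge_distance(self, ancestor: Node, descendant: Node) -> int:
        """Number of edges from ``ancestor`` down to ``descendant``."""
        steps = 0
        node: Node | None = descendant
        while node is not None:
            if node is ancestor:
                return steps
            node = node.parent
            steps += 1
        raise TreeError("nodes are not in an ancestor/descendant relation")

    def suppress_unifurcations(self) -> None:
        for node in list(self.root.postorder()):
            if node is self.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                if node.length is not None and child.length is not None:
                    child.length += node.length
                elif node.length is not None:
                    child.length = node.length
                parent = node.parent
                idx = parent.children.index(node)
                node.children = []
                child.parent = parent
                parent.children[idx] = child
        while len(self.root.children) == 1:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = None

    def prune_leaves(self, labels: Iterable[str]) -> None:
        """Remove the named leaves and suppress resulting unifurcations."""
        labels = set(labels)
        for leaf in self.leaves():
            if leaf.label in labels:
                parent = leaf.parent
                if parent is None:
                    raise TreeError("cannot prune the only node of a tree")
                leaf.detach()
        # drop now-empty internal nodes bottom-up
        changed = True
        while changed:
            changed = False
            for node in list(self.root.postorder()):
                if not node.is_leaf or node.label is not None or node is self.root:
                    continue
                node.detach()
                changed = True
        self.suppress_unifurcations()
        if len(self.root.children) == 2:
            # a trifurcation anchor may have collapsed to a bifurcation
            pass

    def clades(self, include_trivial: bool = False) -> list[frozenset[str]]:
        """Leaf-label sets under each internal node (optionally leaves too)."""
        out = []
        for node in self.postorder():
            if node.is_leaf and not include_trivial:
                continue
            out.append(frozenset(node.leaf_labels()))
        return out

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial unrooted bipartitions of the leaf set."""
        all_leaves = frozenset(self.leaf_labels)
        out: set[frozenset[frozenset[str]]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_labels())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset((side, other)))
        return out

    # -- Newick ----------------------------------------------------------

    def to_newick(self, lengths: bool = True, internal_labels: bool = True,
                  precision: int = 12) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote_label(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if internal_labels and node.label:
                    s += _quote_label(node.label)
            if lengths and node.length is not None and node is not self.root:
                s += f":{node.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only Newick with children sorted by smallest leaf
        label; equal for equal rooted topologies.  Used for deterministic
        tie-breaking."""

        def fmt(node: Node) -> tuple[str, str]:
            if node.is_leaf:
                return node.label, node.label
            parts = sorted(fmt(c) for c in node.children)
            key = parts[0][0]
            return key, "(" + ",".join(p[1] for p in parts) + ")"

        return fmt(self.root)[1] + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves} leaves>"


# -- Newick I/O (dendropy-backed) ------------------------------------------


def _from_dendropy(dtree: "dendropy.Tree", rooted: bool | None) -> PhyloTree:
    def _convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    tree = PhyloTree.__new__(PhyloTree)
    tree.root = root
    tree.rooted = True  # placeholder; set below after unifurcation cleanup
    tree.suppress_unifurcations()
    if rooted is None:
        rooted = len(tree.root.children) == 2
    tree.rooted = rooted
    tree._validate()
    return tree


def parse_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse one Newick string.

    The rooted flag is inferred from the basal degree (bifurcation →
    rooted, trifurcation or polytomy → unrooted) unless ``rooted`` is
    given.  Quoted labels and ``[...]`` comments are handled; malformed
    input raises :class:`NewickError` naming the offending position.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except _NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(str(exc)) from exc
    except _dendropy_error.DataParseError as exc:
        raise NewickError(str(exc)) from exc
    return _from_dendropy(dtree, rooted)


def read_newick_file(path, rooted: bool | None = None) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), rooted=rooted)


def read_newick_list(path, rooted: bool | None = None) -> list[PhyloTree]:
    """Read a file with one Newick tree per statement."""
    try:
        dtrees = dendropy.TreeList.get(path=str(path), schema="newick",
                                       suppress_internal_node_taxa=True)
    except _dendropy_error.DataParseError as exc:
        raise NewickError(str(exc)) from exc
    return [_from_dendropy(t, rooted) for t in dtrees]


def write_newick_file(path, trees: PhyloTree | Sequence[PhyloTree], **kw) -> None:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick(**kw) + "\n")


# -- re-rooting -------------------------------------------------------------


def _adjacency(tree: PhyloTree) -> dict[Node, list[tuple[Node, float | None]]]:
    adj: dict[Node, list[tuple[Node, float | None]]] = {}
    for node in tree.postorder():
        adj.setdefault(node, [])
        for child in node.children:
            adj[node].append((child, child.length))
            adj.setdefault(child, []).append((node, child.length))
    return adj


def unroot(tree: PhyloTree) -> PhyloTree:
    """Return the unrooted view: a rooted root is collapsed into a basal
    trifurcation (the root edge's two halves merged)."""
    t = tree.copy()
    if not t.rooted:
        return t
    root = t.root
    if len(root.children) != 2:
        t.rooted = False
        return t
    a, b = root.children
    keep, merge = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        # two-leaf tree has no unrooted representation beyond itself
        t.rooted = False
        return t
    merge.detach()
    if merge.length is not None and keep.length is not None:
        merge.length += keep.length
    elif keep.length is not None:
        merge.length = keep.length
    keep.add_child(merge)
    keep.detach()
    keep.length = None
    return PhyloTree(keep, rooted=False)


def _reroot_on_edge(adj, parent_end: Node, child_end: Node) -> PhyloTree:
    """Build a rooted tree whose root subdivides the edge
    (parent_end, child_end) of the unrooted topology described by adj."""

    def build(node: Node, come_from: Node, length: float | None) -> Node:
        new = Node(node.label if node.is_leaf else None, length)
        for nbr, ln in adj[node]:
            if nbr is not come_from:
                new.add_child(build(nbr, node, ln))
        return new

    edge_len = None
    for nbr, ln in adj[parent_end]:
        if nbr is child_end:
            edge_len = ln
            break
    half = None if edge_len is None else edge_len / 2.0
    root = Node()
    root.add_child(build(child_end, parent_end, half))
    root.add_child(build(parent_end, child_end, half))
    return PhyloTree(root, rooted=True)


def enumerate_rootings(tree: PhyloTree) -> list[PhyloTree]:
    """All rooted trees obtained by placing the root on each edge of the
    unrooted topology: 2n-3 trees for a binary tree with n leaves."""
    if tree.n_leaves < 3:
        raise TreeError("re-rooting needs at least 3 leaves")
    u = unroot(tree)
    adj = _adjacency(u)
    out = []
    for node in u.postorder():
        for child in node.children:
            out.append(_reroot_on_edge(adj, node, child))
    return out


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance (bipartition symmetric
    difference); 0 means identical unrooted topology."""
    if t1.leaf_labels != t2.leaf_labels:
        raise TreeError("trees must share one leaf set")
    b1 = unroot(t1).bipartitions()
    b2 = unroot(t2).bipartitions()
    return len(b1 ^ b2)


def leaf_label_report(trees: Sequence[PhyloTree]) -> list[tuple[str, int]]:
    """(label, number of trees containing it), sorted by label; the
    validation report written alongside multi-tree inputs."""
    counts: dict[str, int] = {}
    for t in trees:
        for lbl in t.leaf_labels:
            counts[lbl] = counts.get(lbl, 0) + 1
    return sorted(counts.items())
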