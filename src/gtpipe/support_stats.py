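"""Leaf-stability scoring across a tree set, and clade-frequency helpers.

Leaf stability (Thorley & Wilkinson) measures how consistently one taxon
is placed across a collection of trees (typically bootstrap replicates).
For a target taxon t and every unordered triple {a, b, c} of other
leaves, the quartet {t, a, b, c} has three possible unrooted
resolutions: t pairs with a, with b, or with c.  Each resolution's
relative frequency is tallied over the trees that resolve the quartet;
the per-quartet score is either the maximum frequency (``max`` variant)
or the difference between the two highest (``difference``), and the
taxon's stability is the mean over quartets.  Consistently placed taxa
score 1; rogue taxa score low.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .treekit import PhyloTree, unroot

__all__ = ["StabilityReport", "leaf_stability", "leaf_stability_report",
           "quartet_resolution", "clade_frequencies"]


@dataclass
class StabilityReport:
    taxon: str
    score: float
    n_quartets: int
    variant: str
    subsampled: bool
    seed: int | None = None


def _tree_clades(tree: PhyloTree) -> list[frozenset[str]]:
    u = unroot(tree)
    return [frozenset(n.leaf_labels()) for n in u.postorder()
            if n is not u.root]


def quartet_resolution(clades: list[frozenset[str]],
                       quartet: frozenset[str]) -> frozenset[str] | None:
    """The pair that groups together in the induced quartet, as a
    2-element frozenset, or None if the tree does not resolve it.

    A quartet {w,x,y,z} resolves wx|yz iff some edge of the tree has
    exactly {w,x} (or exactly {y,z}) of the quartet on one side.
    """
    for side in clades:
        inside = quartet & side
        if len(inside) == 2:
            return frozenset(inside)
    return None


def leaf_stability(trees: Sequence[PhyloTree], target: str,
                   variant: str = "max",
                   subsample: int | None = 20000,
                   seed: int | None = 0) -> StabilityReport:
    """Leaf-stability score of ``target`` over a tree set.

    Trees lacking some leaf of a quartet simply do not vote on it.  With
    more triples than ``subsample``, a seeded random subset is scored
    (the cubic number of triples is the only reason; pass ``None`` to
    force the full set).
    """
    if variant not in ("max", "difference"):
        raise ValueError("variant must be 'max' or 'difference'")
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    others = sorted(set().union(*(t.leaf_labels for t in trees)) - {target})
    if not any(target in t.leaf_labels for t in trees):
        raise ValueError(f"target {target!r} absent from every tree")
    clade_sets = [_tree_clades(t) for t in trees]
    triples = list(combinations(others, 3))
    subsampled = subsample is not None and len(triples) > subsample
    if subsampled:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(triples), size=subsample, replace=False)
        triples = [triples[i] for i in sorted(idx)]
    scores = []
    for triple in triples:
        quartet = frozenset(triple) | {target}
        counts: dict[frozenset[str], int] = {}
        n_votes = 0
        for tree, clades in zip(trees, clade_sets):
            if not quartet <= tree.leaf_labels:
                continue
            res = quartet_resolution(clades, quartet)
            if res is None:
                continue
            # canonicalise on the pair containing the target
            pair = res if target in res else frozenset(quartet - res)
            counts[pair] = counts.get(pair, 0) + 1
            n_votes += 1
        if n_votes == 0:
            continue
        freqs = sorted((c / n_votes for c in counts.values()), reverse=True)
        if variant == "max":
            scores.append(freqs[0])
        else:
            second = freqs[1] if len(freqs) > 1 else 0.0
            scores.append(freqs[0] - second)
    score = float(np.mean(scores)) if scores else float("nan")
    return StabilityReport(target, score, len(scores), variant, subsampled,
                           seed if subsampled else None)


def leaf_stability_report(trees: Sequence[PhyloTree],
                          variant: str = "max",
                          subsample: int | None = 20000,
                          seed: int | None = 0,
                          ) -> list[StabilityReport]:
    taxa = sorted(set().union(*(t.leaf_labels for t in trees)))
    return [leaf_stability(trees, t, variant, subsample, seed) for t in taxa]


def write_stability_tsv(path, reports: Sequence[StabilityReport]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["taxon", "score", "n_quartets"])
        for r in reports:
            w.writerow([r.taxon, f"{r.score:.6f}", r.n_quartets])


def clade_frequencies(trees: Sequence[PhyloTree]) -> dict[frozenset[str], float]:
    """Fraction of trees containing each clade (rooted clade sets)."""
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for clade in set(t.clades()):
            counts[clade] = counts.get(clade, 0) + 1
    return {c: n / len(trees) for c, n in counts.items()}
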