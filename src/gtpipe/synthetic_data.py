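"""Synthetic gene-family generator.

Emulates the data regime of an EST-based phylogenomic study: a Yule
species tree; gene families evolving along it by a birth–death process
(duplication rate λ, loss rate μ per gene lineage per unit branch
length); taxon-biased missingness from per-taxon sampling probabilities
(EST dropout); alignments with terminal-fragment gaps; and noisy
within-family similarity tables with pseudo E-values, so the clustering,
filtering, masking, reconciliation and search stages can all be
exercised against known ground truth.

The generator records the true event counts it places, which the
reconciliation module must recover exactly in the loss-free,
fully-sampled regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .families import TaxonMap
from .treekit import Node, PhyloTree, write_newick_file

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_alignment",
    "similarity_table",
    "simulate_dataset",
    "taxon_map_for",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
LEAF_SEPARATOR = "|"


@dataclass
class SimulationConfig:
    """One knob set for a full synthetic data set.

    Defaults give the regime the downstream stages are tested under:
    a handful of taxa, moderate duplication/loss, and mild EST dropout.
    """

    n_taxa: int = 7
    speciation_rate: float = 1.0
    duplication_rate: float = 0.2
    loss_rate: float = 0.2
    sampling_probability: float = 0.8
    n_families: int = 100
    alignment_length: int = 120
    substitution_rate: float = 0.3
    fragment_probability: float = 0.3
    fragment_max_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("speciation_rate", "duplication_rate", "loss_rate",
                     "substitution_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sampling_probability", "fragment_probability",
                     "fragment_max_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SimulatedFamily:
    family_id: str
    gene_tree: PhyloTree | None          # true tree after loss pruning + dropout
    n_duplications: int                  # events placed by the simulator
    n_losses: int                        # loss events placed
    traversed_length: float              # total gene-lineage branch length
    dropped_taxa: list[str]
    too_small: bool                      # fewer than 3 surviving leaves
    alignment: dict[str, str] | None = None

    @property
    def leaf_labels(self) -> set[str]:
        return set() if self.gene_tree is None else self.gene_tree.leaf_labels


# -- species tree -----------------------------------------------------------


def simulate_species_tree(n_taxa: int, seed: int,
                          speciation_rate: float = 1.0) -> PhyloTree:
    """Yule tree with ``n_taxa`` leaves labelled T1..Tn.

    Standard forward construction: exponential waiting times at total
    rate (number of lineages × speciation rate); a uniformly chosen tip
    splits; a final waiting-time stretch keeps terminal branches
    positive.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if speciation_rate <= 0:
        raise ValueError("speciation_rate must be positive")
    rng = np.random.default_rng(seed)
    root = Node(length=None)
    active = [root]
    while len(active) < n_taxa:
        k = len(active)
        dt = rng.exponential(1.0 / (speciation_rate * k))
        for tip in active:
            tip.length = (tip.length or 0.0) + dt
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            child = Node(length=0.0)
            split.add_child(child)
            active.append(child)
    dt = rng.exponential(1.0 / (speciation_rate * n_taxa))
    for i, tip in enumerate(active):
        tip.length = (tip.length or 0.0) + dt
    # label tips left-to-right for a stable, readable naming
    tree = PhyloTree.__new__(PhyloTree)
    tree.root = root
    tree.rooted = True
    for i, leaf in enumerate(tree.leaves()):
        leaf.label = f"T{i + 1}"
    tree.root.length = None
    tree._validate()
    return tree


# -- gene family ------------------------------------------------------------


class _GeneSim:
    """Recursive birth–death walk.  Returned nodes carry ``length`` =
    time back to the point where the enclosing call started, so pruned
    speciations and one-sided duplications merge their edges exactly."""

    def __init__(self, dup_rate: float, loss_rate: float,
                 rng: np.random.Generator):
        self.lam = dup_rate
        self.mu = loss_rate
        self.rng = rng
        self.n_dup = 0
        self.n_loss = 0
        self.traversed = 0.0

    def along_branch(self, species_node: Node, remaining: float) -> Node | None:
        """One gene lineage over the last ``remaining`` of a species
        branch; None when every descendant dies."""
        total = self.lam + self.mu
        elapsed = 0.0
        while True:
            wait = (self.rng.exponential(1.0 / total) if total > 0
                    else float("inf"))
            if wait >= remaining:
                self.traversed += remaining
                node = self.at_branch_end(species_node)
                if node is not None:
                    node.length = (node.length or 0.0) + elapsed + remaining
                return node
            self.traversed += wait
            remaining -= wait
            elapsed += wait
            if self.rng.random() * total < self.lam:
                self.n_dup += 1
                left = self.along_branch(species_node, remaining)
                right = self.along_branch(species_node, remaining)
                if left is None and right is None:
                    return None
                if left is None or right is None:
                    survivor = left if right is None else right
                    survivor.length = (survivor.length or 0.0) + elapsed
                    return survivor
                node = Node(length=elapsed)
                node.add_child(left)
                node.add_child(right)
                return node
            self.n_loss += 1
            return None

    def at_branch_end(self, species_node: Node) -> Node | None:
        """The lineage reaches the end of its species branch: sample (at
        a species leaf) or speciate into every daughter branch."""
        if species_node.is_leaf:
            return Node(label=species_node.label, length=0.0)  # copy index later
        children = []
        for sp_child in species_node.children:
            sub = self.along_branch(sp_child, sp_child.length)
            if sub is not None:
                children.append(sub)
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        node = Node(length=0.0)
        for c in children:
            node.add_child(c)
        return node


def simulate_gene_family(species_tree: PhyloTree,
                         dup_rate: float, loss_rate: float,
                         sampling: float, seed: int,
                         family_id: str = "fam",
                         copy_prefix: str = "",
                         separator: str = LEAF_SEPARATOR) -> SimulatedFamily:
    """Birth–death gene evolution down the species tree, then per-taxon
    EST dropout.

    A single gene lineage enters at the species root; on each species
    branch it duplicates at rate λ and dies at rate μ; every lineage
    surviving to a speciation continues into both daughters.  Lost
    subtrees are pruned (unifurcations suppressed); each taxon is then
    kept with the sampling probability, dropping all its copies at once
    (EST libraries miss genes per taxon, not per copy).  Gene leaves are
    named ``<taxon><sep><copy_prefix><copy index>``; pass a family-tagged
    ``copy_prefix`` (e.g. ``"fam0001."``) to make sequence ids unique
    across a multi-family data set.
    """
    for node in species_tree.postorder():
        if node is not species_tree.root and node.length is None:
            raise ValueError("species tree must have branch lengths")
    rng = np.random.default_rng(seed)
    sim = _GeneSim(dup_rate, loss_rate, rng)
    root = sim.at_branch_end(species_tree.root)

    dropped: list[str] = []
    for taxon in sorted(species_tree.leaf_labels):
        if rng.random() > sampling:
            dropped.append(taxon)

    tree: PhyloTree | None = None
    if root is not None:
        counters: dict[str, int] = {}
        survivors = []
        for node in root.postorder():
            if node.is_leaf:
                taxon = node.label
                counters[taxon] = counters.get(taxon, 0) + 1
                node.label = f"{taxon}{separator}{copy_prefix}{counters[taxon]}"
                if taxon not in dropped:
                    survivors.append(node.label)
        if survivors:
            tree = PhyloTree.__new__(PhyloTree)
            tree.root = root
            tree.rooted = True
            tree._validate()
            doomed = tree.leaf_labels - set(survivors)
            if doomed:
                tree.prune_leaves(doomed)
            if tree.n_leaves == 0:
                tree = None
            else:
                tree.root.length = None
    n_leaves = 0 if tree is None else tree.n_leaves
    return SimulatedFamily(
        family_id=family_id,
        gene_tree=tree,
        n_duplications=sim.n_dup,
        n_losses=sim.n_loss,
        traversed_length=sim.traversed,
        dropped_taxa=dropped,
        too_small=n_leaves < 3,
    )


def taxon_of_leaf(label: str, separator: str = LEAF_SEPARATOR) -> str:
    return label.split(separator, 1)[0]


def taxon_map_for(families, species_tree: PhyloTree,
                  groups: dict[str, list[str]] | None = None,
                  separator: str = LEAF_SEPARATOR) -> TaxonMap:
    """Taxon map derived from simulated leaf names; ``groups`` maps a
    taxon to its higher-group tags (synthetic clade labels)."""
    seq_to_taxon = {}
    for fam in families:
        for label in fam.leaf_labels:
            seq_to_taxon[label] = taxon_of_leaf(label, separator)
    taxon_groups = {t: groups.get(t, []) if groups else []
                    for t in species_tree.leaf_labels}
    return TaxonMap(seq_to_taxon, taxon_groups)


# -- alignment + similarity -------------------------------------------------


def simulate_alignment(family: SimulatedFamily, length: int,
                       substitution_rate: float, seed: int,
                       fragment_probability: float = 0.0,
                       fragment_max_fraction: float = 0.5,
                       ) -> dict[str, str]:
    """Evolve an amino-acid alignment down the family's gene tree.

    Single-parameter per-site replacement: along a branch of length b a
    site changes with probability 1 - exp(-rate·b), to a uniformly drawn
    residue.  EST-style fragmentation then gaps out a random prefix or
    suffix of some sequences.  Stores the alignment on the family and
    returns it.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if family.gene_tree is None:
        raise ValueError("cannot align an empty family")
    rng = np.random.default_rng(seed)
    tree = family.gene_tree
    seqs: dict[int, np.ndarray] = {}
    root_seq = rng.choice(AMINO_ACIDS, size=length)
    out: dict[str, str] = {}
    order = list(tree.preorder())
    seqs[id(tree.root)] = root_seq
    for node in order:
        if node is tree.root:
            continue
        parent_seq = seqs[id(node.parent)]
        b = node.length if node.length is not None else 0.0
        p = 1.0 - np.exp(-substitution_rate * b)
        seq = parent_seq.copy()
        hit = rng.random(length) < p
        seq[hit] = rng.choice(AMINO_ACIDS, size=int(hit.sum()))
        seqs[id(node)] = seq
        if node.is_leaf:
            chars = seq.astype("<U1").tolist()
            if rng.random() < fragment_probability:
                cut = int(rng.integers(1, max(2, int(length * fragment_max_fraction) + 1)))
                if rng.random() < 0.5:
                    chars[:cut] = ["-"] * cut
                else:
                    chars[length - cut:] = ["-"] * cut
            out[node.label] = "".join(chars)
    family.alignment = out
    return out


def _pair_score(s1: str, s2: str) -> int:
    return sum(1 for a, b in zip(s1, s2) if a == b and a != "-")


def pseudo_evalue(score: int, scale: float = 2.0) -> float:
    """Monotone map from a similarity score to a pseudo E-value:
    higher score, smaller E-value (floored at 1e-180)."""
    return float(max(10.0 ** (-score / scale), 1e-180))


def similarity_table(families, rng: np.random.Generator,
                     between_pair_fraction: float = 0.05,
                     between_score_max: int = 8,
                     score_noise: float = 2.0,
                     ) -> list[tuple[str, str, float, float]]:
    """Hit-table rows (query, subject, evalue, bitscore).

    Within-family pairs score by shared identical columns of the true
    alignment minus noise; a sparse set of between-family pairs gets low
    scores, giving the E-value cutoff something real to reject.
    """
    rows: list[tuple[str, str, float, float]] = []
    aligned = [f for f in families if f.alignment]
    for fam in aligned:
        ids = sorted(fam.alignment)
        for i, q in enumerate(ids):
            for s in ids[i + 1:]:
                score = _pair_score(fam.alignment[q], fam.alignment[s])
                score = max(1.0, score - abs(rng.normal(0, score_noise)))
                rows.append((q, s, pseudo_evalue(score), float(score)))
    for i, f1 in enumerate(aligned):
        for f2 in aligned[i + 1:]:
            for q in sorted(f1.alignment):
                for s in sorted(f2.alignment):
                    if rng.random() < between_pair_fraction:
                        score = float(rng.integers(1, between_score_max + 1))
                        rows.append((q, s, pseudo_evalue(score), score))
    return rows


# -- full data set ----------------------------------------------------------


def simulate_dataset(config: SimulationConfig,
                     out_dir: str | Path | None = None,
                     ) -> tuple[PhyloTree, list[SimulatedFamily]]:
    """Species tree plus ``n_families`` simulated families (with
    alignments); optionally written to ``out_dir``.

    Per-family seeds are spawned from the config seed, so the whole data
    set is reproduced byte-identically by seed alone.
    """
    species = simulate_species_tree(config.n_taxa, config.seed,
                                    config.speciation_rate)
    seed_seq = np.random.SeedSequence(config.seed)
    fam_seeds = seed_seq.generate_state(2 * config.n_families + 1) % (2 ** 31)
    families: list[SimulatedFamily] = []
    for i in range(config.n_families):
        fam_id = f"fam{i + 1:04d}"
        fam = simulate_gene_family(
            species, config.duplication_rate, config.loss_rate,
            config.sampling_probability, int(fam_seeds[i]),
            family_id=fam_id, copy_prefix=f"{fam_id}.")
        if fam.gene_tree is not None:
            simulate_alignment(
                fam, config.alignment_length, config.substitution_rate,
                int(fam_seeds[config.n_families + i]),
                config.fragment_probability, config.fragment_max_fraction)
        families.append(fam)
    if out_dir is not None:
        write_dataset(Path(out_dir), species, families,
                      int(fam_seeds[-1]))
    return species, families


def write_dataset(out_dir: Path, species: PhyloTree,
                  families: list[SimulatedFamily], hits_seed: int) -> None:
    """FASTA per family, true Newick trees, the hit table, the taxon
    map, and a JSON record of true event counts."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_newick_file(out_dir / "species_tree.nwk", species)
    truth = {}
    tree_lines = []
    fasta_dir = out_dir / "families"
    fasta_dir.mkdir(exist_ok=True)
    for fam in families:
        truth[fam.family_id] = {
            "duplications": fam.n_duplications,
            "losses": fam.n_losses,
            "traversed_length": round(fam.traversed_length, 9),
            "dropped_taxa": fam.dropped_taxa,
            "too_small": fam.too_small,
            "n_leaves": 0 if fam.gene_tree is None else fam.gene_tree.n_leaves,
        }
        if fam.gene_tree is not None:
            tree_lines.append((fam.family_id, fam.gene_tree))
            if fam.alignment:
                with open(fasta_dir / f"{fam.family_id}.fasta", "w") as fh:
                    for sid in sorted(fam.alignment):
                        fh.write(f">{sid}\n{fam.alignment[sid]}\n")
    with open(out_dir / "gene_trees.nwk", "w") as fh:
        for fam_id, tree in tree_lines:
            fh.write(tree.to_newick() + "\n")
    with open(out_dir / "true_events.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    rng = np.random.default_rng(hits_seed)
    rows = similarity_table(families, rng)
    with open(out_dir / "hits.tsv", "w") as fh:
        for q, s, e, b in rows:
            fh.write(f"{q}\t{s}\t{e:.6g}\t{b:.1f}\n")
    taxon_map_for(families, species).to_tsv(out_dir / "taxon_map.tsv")
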