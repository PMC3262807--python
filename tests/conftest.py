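import numpy as np
import pytest
from hypothesis import settings

from gtpipe.families import TaxonMap
from gtpipe.treekit import Node, PhyloTree

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def random_rooted_tree(labels, rng: np.random.Generator,
                       lengths: bool = False) -> PhyloTree:
    """Random binary rooted topology by iterative pair joining."""
    nodes = [Node(l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = Node()
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    tree = PhyloTree(nodes[0], rooted=True)
    if lengths:
        for node in tree.postorder():
            if node is not tree.root:
                node.length = float(rng.uniform(0.05, 2.0))
    return tree


def random_gene_tree(species_labels, n_genes: int, rng: np.random.Generator,
                     lengths: bool = False) -> tuple[PhyloTree, TaxonMap]:
    """Random gene tree whose leaves draw taxa (with replacement) from the
    species set; returns the tree and a matching taxon map."""
    counts: dict[str, int] = {}
    gene_labels = []
    seq_to_taxon = {}
    for _ in range(n_genes):
        taxon = str(rng.choice(species_labels))
        counts[taxon] = counts.get(taxon, 0) + 1
        label = f"{taxon}|{counts[taxon]}"
        gene_labels.append(label)
        seq_to_taxon[label] = taxon
    tree = random_rooted_tree(gene_labels, rng, lengths=lengths)
    return tree, TaxonMap(seq_to_taxon)


@pytest.fixture
def simple_taxa() -> TaxonMap:
    return TaxonMap(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "d1": "D"},
        {"A": {"Nematoda"}, "B": {"Arthropoda"}, "C": {"Annelida"},
         "D": {"Platyhelminthes"}},
    )
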