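# Methods

## Reconciliation model

Gene trees are reconciled against a rooted species tree by the LCA
(most-recent-common-ancestor) mapping, computed in one postorder pass.
Event labels and loss counts follow the classical duplication–loss
model: an internal gene node is a duplication exactly when it maps to
the same species node as one of its children; a duplication at species
node *s* with children mapped d₁ and d₂ edges below contributes
d₁ + d₂ losses, a speciation contributes (d₁ − 1) + (d₂ − 1).  No
losses are charged above the gene-tree root, because nothing is known
about the family outside its root.  Both counts are topology-only:
branch lengths never enter the cost.

Two cost models are exposed.  `dup` (duplications only) is the default
because it is the criterion classic gene-tree-parsimony search software
optimises; `duploss` (D + L) is available everywhere the model is a
parameter.  The test suite verifies, by exhaustive dynamic programming
over *all* valid mappings, that the LCA map attains the minimum of both
D and D + L.  One definitional point is worth recording: "all valid
mappings" must label a node a speciation only when its two child
lineages descend through distinct daughters of its image — if
speciation status were granted merely by inequality of images, an
enumeration could relabel any duplication one node higher and undercut
the true minimum by one.  The package itself computes events only at
the LCA map, where the two formulations coincide.

Unrooted gene trees are scored by their best rooting: the unrooted
topology is re-rooted on each of its 2n − 3 edges and the minimum cost
taken (ties resolved toward the lexicographically smallest canonical
Newick, so results are reproducible).  Outgroup rooting is a separate,
taxonomy-driven operation: a priority list of group tags (default
Nematoda, then Arthropoda) is scanned, the tree is rooted on the edge
isolating the highest-priority group present (on the clade edge when
the group's leaves form a clade in some rooting, else on the terminal
edge of the first such leaf by id), and a family with no outgroup at
all is returned unrooted-flagged — a legitimate outcome handled
downstream by rooting optimisation, not an error.

## Species-tree search

`total_cost` sums per-family reconciliation costs; the per-family
breakdown is always reported so cost provenance can be audited.  Three
rooting policies exist: `fixed` (every tree contributes its rooted
cost), `optimize-all` (every tree is minimised over rootings, matching
the behaviour of re-rooting reconciliation software), and the default
`optimize-unrooted-only`.

`brute_force_gtp` enumerates all (2n − 3)!! rooted topologies by
stepwise leaf addition and returns every argmin; it is the oracle for
up to 8 taxa (135,135 topologies) and the reference the heuristic is
validated against.  `heuristic_search` hill-climbs over the rooted SPR
neighbourhood (every non-root subtree regrafted onto every edge outside
it, including above the root) from random taxon-addition starting
trees; the move taken is the best strictly improving neighbour, ties
again by canonical Newick.  Restarts (default 10 in search contexts, 5
in the pipeline) plus a fixed seed make runs deterministic.  Costs are
recomputed per candidate tree from pre-compiled gene-tree arrays; on
desk-scale problems (≤ 31 taxa, hundreds of families) this is fast
enough that incremental cost updates are an optimisation, not a
requirement.

Bootstrap GTP pools all per-family bootstrap trees into one gene-tree
list, searches once, and stars each clade of the main species tree that
recurs in the bootstrap species tree.  No other confidence measure is
attached to GTP trees; none is established.

## Clustering

Hit tables (query, subject, E-value, optional bitscore) become an
undirected graph: edges kept at E ≤ 1e-10 by default, reciprocal hits
merged keeping the best E-value, weight −log₁₀E capped at 200 for
E = 0.  Markov clustering uses expansion 2, inflation 5 (the
fine-grained setting this pipeline is built around), self-loops at each
vertex's maximum incident weight, and pruning of entries below 1e-5 —
applied to the *renormalised* matrix, then column sums restored;
pruning the raw inflated matrix annihilates the uniform columns that
perfect cliques converge to.  Attractor rows sharing support are merged
into attractor systems; each vertex joins the system with the largest
attraction, ties to the system whose smallest member id sorts first.
Non-convergence within `max_iter` returns the current clustering with a
warning flag rather than failing.

## Family filtering and representatives

The retention rule has three clauses, each auditable per family: at
least one member of a focal group (default `Myzostomida`), at least
`min_size` members (default 3), and full coverage of at least one
group-set alternative (default {Annelida, Platyhelminthes} or
{Trochozoa, Platyzoa}).  Group tags are data (taxon-map file), not
code.

For the supermatrix track a family is usable when every taxon is
single-copy or its copies form a clade (in-paralogs, which carry no
signal about the species tree); the copy with the shortest terminal
branch represents the taxon, ties to the smallest sequence id.  On an
unrooted gene tree "forms a clade" means "lies on one side of some
edge".  Missing branch lengths in a multi-copy clade are an error, not
a silent default, since the choice would otherwise be arbitrary.

## Masking and concatenation

Column masking removes high-gap columns at a threshold (default 0.70).
Both natural readings of the boundary are implemented: `inclusive`
drops a column whose gap fraction is ≥ the threshold (supermatrix
default), `strict` only when it exceeds it (per-gene default).  A
10-row column with exactly 7 gaps therefore goes in one mode and stays
in the other; tests pin this.  Masking runs after concatenation for the
supermatrix track (per-gene order is also supported).  Concatenation
lays genes left to right, gap-fills absent taxon×gene blocks, emits a
1-based-inclusive RAxML-style partition file, and reports per-taxon
non-gap counts (the coverage barplot data).  N50 is the largest L such
that contigs ≥ L sum to at least half the assembly; the N50 contig
count is the number of contigs at least that long.

## Synthetic data generator

The generator emulates the statistical structure of an EST-based
phylogenomic data set, not any particular organism:

* **Species tree** — Yule process (rate 1.0/unit time), n ≥ 3 taxa,
  labels T1..Tn, a final exponential stretch keeping tip branches
  positive.
* **Gene families** — one lineage enters at the species root;
  duplication rate λ and loss rate μ per gene lineage per unit branch
  length; every lineage surviving to a speciation enters both
  daughters.  Lost subtrees are pruned with edge lengths merged
  exactly, so surviving-tree branch lengths are the true elapsed times.
  The simulator records events *placed* (not surviving), total
  gene-lineage length traversed (so the mean duplication count can be
  checked against λ·length analytically), and the drop list.
* **Dropout** — each taxon is kept with probability `sampling`
  (default 0.8); all copies of a dropped taxon vanish at once,
  mimicking a missing EST library rather than per-copy loss.  Families
  left with < 3 leaves are flagged, not deleted, so downstream size
  filters are exercised.
* **Alignments** — single-parameter per-site replacement over the
  20-letter amino-acid alphabet (change probability 1 − e^(−r·b) per
  branch, default r = 0.3), then EST-style fragmentation gapping a
  random prefix or suffix (default: 30% of sequences, up to half the
  length).  No rate heterogeneity, no indel model, no codon structure —
  downstream stages test topology and counting logic, not model fit.
* **Similarity tables** — within-family scores from shared identical
  columns minus half-normal noise, mapped to pseudo E-values by
  E = 10^(−score/2) (floored at 1e-180), so the 1e-10 cutoff is a real
  discriminator; sparse between-family pairs draw low scores above the
  cutoff.  At the default substitution rate, genuine within-family
  pairs at typical Yule depths clear the cutoff comfortably, mirroring
  a regime where true homologs are retained.

Defaults (7 taxa, 100 families, λ = μ = 0.2, sampling 0.8, length 120)
are the regime the acceptance checks run under; they were chosen once
as a plausible desk-scale miniature of a transcriptome study and are
all overridable via `SimulationConfig`.  Determinism is strict: one
seed fans out to per-family seeds through `SeedSequence`, and a config
reproduces every output file byte for byte.

Simulated sequence ids are `<taxon>|<famNNNN.copy>` at data-set level
(the taxon is always the leading field) so that ids stay unique across
families, which the clustering stage requires.

What passing tests on this generator does **not** show: robustness to
alignment error, model misspecification, rate heterogeneity across
sites or lineages, incomplete lineage sorting, or horizontal transfer —
none of which the generator produces.

## Pipeline

`run_pipeline` chains the stages (simulate → cluster → filter → NJ gene
trees → rooting → supermatrix track and GTP track → leaf stability),
writing one JSON manifest per stage with parameters and SHA-256 output
checksums; reruns with a config and seed reproduce the manifests byte
for byte, and `resume=True` skips stages whose outputs verify.  The NJ
stand-in estimates gene trees from p-distances over shared non-gap
columns (zero-overlap pairs are an error; negative NJ branch lengths
are clamped to zero with a warning).  MCL clusters that span several
source alignments are excluded from the tree-building stages because
the pipeline does not compute new multiple alignments; with the default
generator settings this is rare.  Leaf stability is computed on
one-leaf-per-taxon reductions of the gene trees, `max` variant, triples
capped at 20,000 per taxon (seeded subsampling) against the cubic
blow-up of quartet enumeration.

## Numerical and degenerate-input conventions

* Branch lengths absent are missing, never zero; operations needing
  them raise.
* All tie-breaks (representative choice, rooting, SPR moves, family
  numbering) resolve lexicographically so that equal inputs give equal
  outputs.
* MCL convergence tolerance 1e-8 on the entry-wise change; clusters are
  read from attractor support at the same tolerance.
* Canonical Newick (children sorted by smallest descendant label) is
  the equality notion for rooted topologies; unrooted comparisons use
  bipartition sets (Robinson–Foulds).

## Problem sizes used in the checks

Acceptance-style checks run at desk scale: ≤ 10-leaf gene trees against
≤ 6-taxon species trees for the mapping oracle (200 pairs), 5–6-taxon
20-family problems for heuristic-vs-brute-force (30 problems), and
7-taxon 100-family replicates for recovery (20 replicates).  These
sizes keep exhaustive enumeration exact while leaving every code path
identical to larger runs.
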