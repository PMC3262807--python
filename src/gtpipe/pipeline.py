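"""End-to-end orchestration of the synthetic gene-family pipeline, plus
the neighbour-joining gene-tree estimator that lets the whole thing run
with no external alignment/ML tools.

Stages (similarity clustering → family filtering → a supermatrix track
and a gene-tree-parsimony track) write their outputs and a JSON manifest
(parameters + output checksums) into one run directory; a rerun with the
same config and seed reproduces every manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from . import clustering, families, gtp_search, reconcile, support_stats, supermatrix
from .families import FamilyFilterRule, TaxonMap
from .synthetic_data import SimulationConfig, simulate_dataset
from .treekit import (PhyloTree, parse_newick, read_newick_list,
                      robinson_foulds, write_newick_file)

__all__ = ["PipelineConfig", "nj_tree", "run_pipeline", "p_distance_matrix"]


# -- neighbour joining ------------------------------------------------------


def p_distance_matrix(aln: dict[str, str], gap_chars: str = "-") -> DistanceMatrix:
    """Pairwise p-distances over columns where both rows are non-gap."""
    ids = sorted(aln)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    mat = np.array([list(aln[i]) for i in ids], dtype="<U1")
    gaps = np.isin(mat, list(gap_chars))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gaps[i] & ~gaps[j]
            if not shared.any():
                raise ValueError(
                    f"sequences {ids[i]!r} and {ids[j]!r} share no columns")
            d[i, j] = d[j, i] = float(
                (mat[i, shared] != mat[j, shared]).mean())
    return DistanceMatrix(d, ids)


def nj_tree(aln: dict[str, str], gap_chars: str = "-") -> PhyloTree:
    """Neighbour-joining tree from p-distances; the stand-in for
    per-family ML gene-tree estimation.

    Returns an unrooted tree; negative branch lengths (an NJ artefact)
    are clamped to zero with a warning.
    """
    dm = p_distance_matrix(aln, gap_chars)
    if np.allclose(dm.data, 0):
        warnings.warn("all sequences identical: arbitrary star resolution "
                      "with zero branch lengths")
    skt = _skbio_nj(dm)
    tree = parse_newick(str(skt).strip(), rooted=False)
    clamped = False
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return tree


# -- configuration ----------------------------------------------------------


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the study settings (E-value
    cutoff 1e-10, inflation 5, family size >= 3, 70% gap masking,
    Nematoda/Arthropoda outgroup priority, duplication-only cost)."""

    out_dir: str = "run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    # clustering
    evalue_cutoff: float = 1e-10
    inflation: float = 5.0
    # family filtering
    focal_group: str = "Myzostomida"
    min_family_size: int = 3
    coverage_alternatives: tuple = (("Annelida", "Platyhelminthes"),
                                    ("Trochozoa", "Platyzoa"))
    # masking
    mask_threshold: float = 0.7
    supermatrix_mask_mode: str = "inclusive"
    genetree_mask_mode: str = "strict"
    # rooting / GTP
    rooting_priority: tuple = ("Nematoda", "Arthropoda")
    cost_model: str = "dup"
    restarts: int = 5
    max_rounds: int = 50
    run_bootstrap_gtp: bool = False
    run_leaf_stability: bool = True
    # externally supplied gene trees (skip the NJ stage)
    gene_trees_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def filter_rule(self) -> FamilyFilterRule:
        return FamilyFilterRule(
            focal_group=self.focal_group,
            min_size=self.min_family_size,
            coverage_alternatives=tuple(frozenset(a)
                                        for a in self.coverage_alternatives))


# -- manifests --------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, out_dir: Path, resume: bool):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.resume = resume

    def manifest_path(self, stage: str) -> Path:
        return self.dir / f"manifest_{stage}.json"

    def done(self, stage: str, outputs: list[Path]) -> bool:
        mpath = self.manifest_path(stage)
        if not (self.resume and mpath.exists()):
            return False
        recorded = json.loads(mpath.read_text()).get("outputs", {})
        return all(p.exists() and recorded.get(p.name) == _sha256(p)
                   for p in outputs)

    def write_manifest(self, stage: str, params: dict,
                       outputs: list[Path]) -> None:
        manifest = {
            "stage": stage,
            "parameters": params,
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        self.manifest_path(stage).write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n")


# -- the pipeline -----------------------------------------------------------


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Run every stage; returns the run directory.

    With a simulation config the input data is generated first;
    otherwise ``out_dir`` must already contain ``hits.tsv``,
    ``taxon_map.tsv`` and per-family FASTA alignments (the formats the
    synthetic writer emits).
    """
    out = Path(config.out_dir)
    run = _Run(out, resume)
    sim_tree = None

    # stage: simulate ------------------------------------------------------
    if config.simulation is not None:
        cfg = config.simulation
        outputs = [out / "species_tree.nwk", out / "hits.tsv",
                   out / "taxon_map.tsv", out / "true_events.json",
                   out / "gene_trees.nwk"]
        if not run.done("simulate", outputs):
            sim_tree, fams = simulate_dataset(cfg, out_dir=out)
            run.write_manifest("simulate", asdict(cfg), outputs)
        else:
            sim_tree = read_newick_list(out / "species_tree.nwk")[0]

    taxa = TaxonMap.from_tsv(out / "taxon_map.tsv")

    # stage: cluster -------------------------------------------------------
    fam_tsv = out / "families.tsv"
    if not run.done("cluster", [fam_tsv]):
        hits = clustering.read_hit_table(out / "hits.tsv")
        graph = clustering.build_similarity_graph(hits, config.evalue_cutoff)
        assignment = clustering.mcl_cluster(graph, inflation=config.inflation)
        assignment.to_frame().to_csv(fam_tsv, sep="\t", index=False)
        run.write_manifest("cluster", {"evalue_cutoff": config.evalue_cutoff,
                                       "inflation": config.inflation},
                           [fam_tsv])
    fam_frame = pd.read_csv(fam_tsv, sep="\t")
    fam_members: dict[str, list[str]] = {}
    for seq, fam in fam_frame.itertuples(index=False):
        fam_members.setdefault(fam, []).append(seq)

    # stage: filter --------------------------------------------------------
    audit_tsv = out / "family_audit.tsv"
    rule = config.filter_rule()
    usable_groups = {g for t in taxa.taxa() for g in taxa.groups_of(t)}
    if not usable_groups:
        # synthetic taxa carry no group tags: retain by size only
        rule = FamilyFilterRule(
            focal_group="__any__", min_size=config.min_family_size,
            coverage_alternatives=(frozenset(),))
        tagged = TaxonMap(taxa.seq_to_taxon,
                          {t: {"__any__"} for t in taxa.taxa()})
    else:
        tagged = taxa
    retained, audits = families.filter_families(fam_members, tagged, rule)
    families.write_audit_tsv(audit_tsv, audits)
    run.write_manifest("filter", {"rule": {
        "focal_group": rule.focal_group, "min_size": rule.min_size,
        "coverage_alternatives": sorted(map(sorted, rule.coverage_alternatives))}},
        [audit_tsv])

    # stage: gene trees (NJ or user-supplied) ------------------------------
    genetree_file = out / "estimated_gene_trees.nwk"
    fasta_dir = out / "families"
    source_aln: dict[str, dict[str, str]] = {}
    seq_source: dict[str, str] = {}
    if fasta_dir.exists():
        for p in sorted(fasta_dir.glob("*.fasta")):
            aln = supermatrix.read_fasta_alignment(p)
            source_aln[p.stem] = aln
            for sid in aln:
                seq_source[sid] = p.stem
    # a cluster is usable when all its members come from one source
    # alignment (clusters merging several sources would need a fresh
    # alignment, which this pipeline does not compute)
    fam_alignments: dict[str, dict[str, str]] = {}
    for fam_id in retained:
        sources = {seq_source.get(s) for s in fam_members[fam_id]}
        if len(sources) == 1 and None not in sources:
            src = sources.pop()
            fam_alignments[fam_id] = {
                s: source_aln[src][s] for s in sorted(fam_members[fam_id])}

    gene_trees: dict[str, PhyloTree] = {}
    if config.gene_trees_file:
        trees = read_newick_list(config.gene_trees_file)
        for fam_id, tree in zip(sorted(fam_alignments), trees):
            gene_trees[fam_id] = tree
        run.write_manifest("genetrees", {"source": "external"}, [])
    else:
        masked_for_trees: dict[str, supermatrix.MaskedAlignment] = {}
        for fam_id, aln in sorted(fam_alignments.items()):
            masked = supermatrix.mask_alignment(
                aln, config.mask_threshold, config.genetree_mask_mode)
            if masked.n_columns == 0 or len(masked.ids) < 3:
                continue
            masked_for_trees[fam_id] = masked
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gene_trees[fam_id] = nj_tree(masked.to_dict())
        write_newick_file(genetree_file, list(gene_trees.values()))
        run.write_manifest("genetrees",
                           {"method": "nj", "mask": config.genetree_mask_mode,
                            "threshold": config.mask_threshold},
                           [genetree_file])

    # stage: rooting -------------------------------------------------------
    priority = [g for g in config.rooting_priority if g in usable_groups]
    rooted_trees: list[PhyloTree] = []
    n_unrooted = 0
    for fam_id in sorted(gene_trees):
        tree = gene_trees[fam_id]
        if priority:
            tree = reconcile.root_by_outgroup(tree, taxa, priority)
        if not tree.rooted:
            n_unrooted += 1
        rooted_trees.append(tree)
    run.write_manifest("root", {"priority": list(priority),
                                "n_unrooted": n_unrooted}, [])

    # stage: supermatrix track --------------------------------------------
    phylip = out / "supermatrix.phy"
    partitions = out / "partitions.txt"
    coverage = out / "coverage.tsv"
    reps_tsv = out / "representatives.tsv"
    blocks = []
    rep_rows = []
    taxon_order = sorted(taxa.taxa())
    for fam_id, tree in sorted(gene_trees.items()):
        if fam_id not in fam_alignments:
            continue
        reps = families.select_representatives(tree, taxa)
        if reps is None:
            continue
        rep_rows.extend((fam_id, t, s) for t, s in sorted(reps.items()))
        aln = fam_alignments[fam_id]
        rows = {seq_id: aln[seq_id] for seq_id in reps.values()}
        masked = supermatrix.mask_alignment(
            rows, config.mask_threshold, config.supermatrix_mask_mode)
        row_taxon = {seq_id: t for t, seq_id in reps.items()}
        blocks.append((fam_id, masked, row_taxon))
    families.write_representatives_tsv(reps_tsv, rep_rows)
    if blocks:
        sm = supermatrix.concatenate(blocks, taxon_order)
        sm.write_phylip(phylip)
        sm.write_partitions(partitions)
        sm.write_coverage_tsv(coverage)
        run.write_manifest("supermatrix",
                           {"n_genes": len(blocks),
                            "mode": config.supermatrix_mask_mode,
                            "threshold": config.mask_threshold,
                            "n_columns": sm.n_columns},
                           [phylip, partitions, coverage, reps_tsv])
    else:
        run.write_manifest("supermatrix", {"n_genes": 0}, [reps_tsv])

    # stage: GTP -----------------------------------------------------------
    species_out = out / "gtp_species_tree.nwk"
    costs_tsv = out / "gtp_costs.tsv"
    trace_json = out / "gtp_trace.json"
    usable = [t for t in rooted_trees if t.n_leaves >= 3]
    problem = gtp_search.GtpProblem(
        usable, taxa, model=config.cost_model,
        rooting="optimize-unrooted-only", restarts=config.restarts,
        seed=config.seed, max_rounds=config.max_rounds)
    result = gtp_search.heuristic_search(problem)
    write_newick_file(species_out, result.best_tree)
    with open(costs_tsv, "w") as fh:
        fh.write("tree_index\tcost\n")
        for i, c in enumerate(result.breakdown):
            fh.write(f"{i}\t{c}\n")
    trace_json.write_text(json.dumps(
        {"best_cost": result.best_cost,
         "trace": [list(t) for t in result.trace]}, indent=1) + "\n")
    summary = {"best_cost": result.best_cost, "n_gene_trees": len(usable)}
    if sim_tree is not None:
        summary["rf_to_true_tree"] = robinson_foulds(result.best_tree, sim_tree)
    run.write_manifest("gtp", {"model": config.cost_model,
                               "restarts": config.restarts,
                               "seed": config.seed, **summary},
                       [species_out, costs_tsv, trace_json])

    # stage: leaf stability ------------------------------------------------
    if config.run_leaf_stability and len(usable) >= 2:
        taxon_trees = []
        for t in usable:
            # collapse to one leaf per taxon for the stability tally
            keep: dict[str, str] = {}
            for lbl in sorted(t.leaf_labels):
                tx = taxa.taxon_of(lbl)
                if tx not in keep:
                    keep[tx] = lbl
            tt = t.copy()
            tt.prune_leaves(t.leaf_labels - set(keep.values()))
            for leaf in tt.leaves():
                leaf.label = taxa.taxon_of(leaf.label)
            if tt.n_leaves >= 4:
                taxon_trees.append(tt)
        if len(taxon_trees) >= 2:
            reports = support_stats.leaf_stability_report(
                taxon_trees, seed=config.seed)
            support_stats.write_stability_tsv(out / "leaf_stability.tsv",
                                              reports)
            run.write_manifest("leaf_stability", {"variant": "max"},
                               [out / "leaf_stability.tsv"])

    return out
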