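import numpy as np
import pytest

from gtpipe.reconcile import count_events
from gtpipe.synthetic_data import (SimulationConfig, pseudo_evalue,
                                   similarity_table, simulate_alignment,
                                   simulate_dataset, simulate_gene_family,
                                   simulate_species_tree, taxon_map_for)
from gtpipe.treekit import robinson_foulds


class TestSpeciesTree:
    def test_minimal_tree_shape(self):
        t = simulate_species_tree(3, seed=0)
        assert t.n_leaves == 3
        assert sum(1 for n in t.postorder() if not n.is_leaf) == 2
        assert t.rooted and t.is_binary()

    def test_seed_determinism(self):
        a = simulate_species_tree(8, seed=42)
        b = simulate_species_tree(8, seed=42)
        assert a.to_newick() == b.to_newick()
        c = simulate_species_tree(8, seed=43)
        assert a.to_newick() != c.to_newick()

    def test_taxon_count_scales_to_study_size(self):
        t = simulate_species_tree(31, seed=1)
        assert t.n_leaves == 31
        assert t.leaf_labels == {f"T{i}" for i in range(1, 32)}

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(2, seed=0)

    def test_branch_lengths_positive(self):
        t = simulate_species_tree(10, seed=7)
        assert all(n.length > 0 for n in t.postorder() if n is not t.root)


class TestGeneFamily:
    def test_no_events_reproduces_species_topology(self):
        sp = simulate_species_tree(7, seed=1)
        fam = simulate_gene_family(sp, 0.0, 0.0, 1.0, seed=2)
        assert fam.n_duplications == 0 and fam.n_losses == 0
        assert fam.gene_tree.n_leaves == 7
        relabeled = fam.gene_tree.copy()
        for leaf in relabeled.leaves():
            leaf.label = leaf.label.split("|")[0]
        assert robinson_foulds(relabeled, sp) == 0

    def test_zero_sampling_gives_flagged_empty_family(self):
        sp = simulate_species_tree(5, seed=1)
        fam = simulate_gene_family(sp, 0.0, 0.0, 0.0, seed=3)
        assert fam.gene_tree is None
        assert fam.too_small
        assert len(fam.dropped_taxa) == 5

    def test_duplication_count_matches_analytical_expectation(self):
        """Mean placed duplications ~= lambda * mean traversed gene-lineage
        length, within 3 standard errors over 500 replicates."""
        sp = simulate_species_tree(7, seed=5)
        lam = 0.3
        dups, lengths = [], []
        for s in range(500):
            fam = simulate_gene_family(sp, lam, 0.3, 1.0, seed=s)
            dups.append(fam.n_duplications)
            lengths.append(fam.traversed_length)
        dups = np.array(dups, dtype=float)
        expected = lam * np.array(lengths)
        diff = dups - expected
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * se

    def test_conservation_of_internal_nodes_without_loss(self):
        """With mu=0 and full sampling: duplications placed == internal
        nodes minus species-induced bifurcations."""
        sp = simulate_species_tree(6, seed=9)
        for s in range(20):
            fam = simulate_gene_family(sp, 0.4, 0.0, 1.0, seed=s)
            internal = sum(1 for n in fam.gene_tree.postorder()
                           if not n.is_leaf)
            n_leaves = fam.gene_tree.n_leaves
            # binary tree: internal = leaves - 1; speciation nodes are the
            # non-duplication internals
            assert fam.n_duplications == internal - (n_leaves - 1
                                                     - fam.n_duplications)

    def test_reconciler_recovers_recorded_events_without_loss(self):
        """End-to-end oracle: mu=0, full sampling -> reconciled D equals
        the simulator's count and L == 0."""
        sp = simulate_species_tree(7, seed=11)
        for s in range(50):
            fam = simulate_gene_family(sp, 0.3, 0.0, 1.0, seed=s)
            taxa = taxon_map_for([fam], sp)
            res = count_events(fam.gene_tree, sp, taxa)
            assert res.duplications == fam.n_duplications
            assert res.losses == 0

    def test_missing_branch_lengths_rejected(self):
        from gtpipe.treekit import parse_newick
        sp = parse_newick("((T1,T2),T3);")
        with pytest.raises(ValueError, match="branch length"):
            simulate_gene_family(sp, 0.1, 0.1, 1.0, seed=0)


class TestAlignmentAndSimilarity:
    def test_zero_rate_no_fragmentation_gives_identical_rows(self):
        sp = simulate_species_tree(5, seed=1)
        fam = simulate_gene_family(sp, 0.2, 0.0, 1.0, seed=4)
        aln = simulate_alignment(fam, 50, substitution_rate=0.0, seed=5)
        rows = set(aln.values())
        assert len(rows) == 1
        assert "-" not in rows.pop()

    def test_two_families_separate_under_clustering(self):
        """Between-family scores below every within-family score make the
        similarity graph two components -> exactly two MCL clusters."""
        import networkx as nx

        from gtpipe.clustering import build_similarity_graph, mcl_cluster
        sp = simulate_species_tree(5, seed=1)
        fams = []
        for i, s in enumerate((21, 22)):
            fam = simulate_gene_family(sp, 0.1, 0.0, 1.0, seed=s,
                                       family_id=f"f{i}", copy_prefix=f"f{i}.")
            simulate_alignment(fam, 100, 0.1, seed=s)
            fams.append(fam)
        rows = similarity_table(fams, np.random.default_rng(0),
                                between_pair_fraction=0.3,
                                between_score_max=5)
        import pandas as pd
        hits = pd.DataFrame(rows, columns=["query", "subject",
                                           "evalue", "bitscore"])
        graph = build_similarity_graph(hits, evalue_cutoff=1e-10)
        assignment = mcl_cluster(graph, inflation=5)
        clusters = sorted(map(sorted, assignment.families.values()))
        expected = sorted(map(sorted, (f.leaf_labels for f in fams)))
        assert clusters == expected

    def test_pseudo_evalue_monotone_in_score(self):
        evs = [pseudo_evalue(s) for s in range(0, 100, 5)]
        assert evs == sorted(evs, reverse=True)

    def test_invalid_length_rejected(self):
        sp = simulate_species_tree(5, seed=1)
        fam = simulate_gene_family(sp, 0.0, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_alignment(fam, 0, 0.1, seed=0)


class TestDataset:
    def test_byte_identical_outputs_for_one_seed(self, tmp_path):
        cfg = SimulationConfig(n_taxa=5, n_families=10, seed=77)
        simulate_dataset(cfg, out_dir=tmp_path / "a")
        simulate_dataset(cfg, out_dir=tmp_path / "b")
        for name in ("species_tree.nwk", "hits.tsv", "taxon_map.tsv",
                     "true_events.json", "gene_trees.nwk"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name

    def test_sequence_ids_unique_across_families(self):
        cfg = SimulationConfig(n_taxa=5, n_families=15, seed=3)
        _, fams = simulate_dataset(cfg)
        seen = set()
        for fam in fams:
            labels = fam.leaf_labels
            assert not labels & seen
            seen |= labels

    def test_small_families_flagged_not_dropped(self):
        cfg = SimulationConfig(n_taxa=4, n_families=40,
                               sampling_probability=0.3, seed=5)
        _, fams = simulate_dataset(cfg)
        assert len(fams) == 40
        assert any(f.too_small for f in fams)
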