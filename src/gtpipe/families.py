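"""Gene-family selection and single-copy representative extraction.

Families produced by the clustering step go through two screens:

* a coverage filter (focal-group presence, minimum size, and clade
  coverage alternatives) selecting families worth aligning at all, and
* a single-copy screen for the supermatrix track, where a taxon with
  several copies is admitted only when those copies form a clade of the
  gene tree (in-paralogs, which carry no information about the species
  tree) and is then represented by the copy with the shortest terminal
  branch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .treekit import PhyloTree

__all__ = [
    "TaxonMap",
    "FamilyFilterRule",
    "FilterAudit",
    "filter_families",
    "taxon_copy_profile",
    "select_representatives",
    "RepresentativeError",
]


class RepresentativeError(ValueError):
    """Raised when representative selection cannot be carried out."""


class TaxonMap:
    """Sequence-id → taxon and taxon → higher-group assignments.

    The group vocabulary (e.g. ``Myzostomida``, ``Annelida``,
    ``Trochozoa``, ``Platyzoa``, ``Nematoda``, ``Arthropoda``) is data,
    not code: it comes from the map file or from the caller.
    """

    def __init__(self,
                 seq_to_taxon: Mapping[str, str],
                 taxon_groups: Mapping[str, Iterable[str]] | None = None):
        self.seq_to_taxon = dict(seq_to_taxon)
        self.taxon_groups: dict[str, frozenset[str]] = {
            t: frozenset(g) for t, g in (taxon_groups or {}).items()
        }
        for taxon in set(self.seq_to_taxon.values()):
            self.taxon_groups.setdefault(taxon, frozenset())

    # -- lookups --------------------------------------------------------

    def taxon_of(self, seq_id: str) -> str:
        try:
            return self.seq_to_taxon[seq_id]
        except KeyError:
            raise KeyError(f"sequence id {seq_id!r} has no taxon assignment")

    def groups_of(self, taxon: str) -> frozenset[str]:
        return self.taxon_groups.get(taxon, frozenset())

    def seq_groups(self, seq_id: str) -> frozenset[str]:
        return self.groups_of(self.taxon_of(seq_id))

    def taxa(self) -> set[str]:
        return set(self.taxon_groups)

    def unresolvable(self, seq_ids: Iterable[str]) -> list[str]:
        return sorted(s for s in seq_ids if s not in self.seq_to_taxon)

    # -- I/O ------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "TaxonMap":
        """Read a 3-column TSV: sequence_id, taxon, semicolon-separated
        group tags (third column may be empty)."""
        seq_to_taxon: dict[str, str] = {}
        taxon_groups: dict[str, set[str]] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                seq_id, taxon = row[0], row[1]
                seq_to_taxon[seq_id] = taxon
                groups = taxon_groups.setdefault(taxon, set())
                if len(row) > 2 and row[2]:
                    groups.update(g for g in row[2].split(";") if g)
        return cls(seq_to_taxon, taxon_groups)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for seq_id in sorted(self.seq_to_taxon):
                taxon = self.seq_to_taxon[seq_id]
                w.writerow([seq_id, taxon, ";".join(sorted(self.groups_of(taxon)))])


@dataclass(frozen=True)
class FamilyFilterRule:
    """Retention rule: the family must contain the focal group, reach the
    minimum size, and fully cover at least one of the coverage
    alternatives (each alternative is a set of group tags that must all
    be present)."""

    focal_group: str = "Myzostomida"
    min_size: int = 3
    coverage_alternatives: tuple[frozenset[str], ...] = (
        frozenset({"Annelida", "Platyhelminthes"}),
        frozenset({"Trochozoa", "Platyzoa"}),
    )

    def __post_init__(self):
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not self.coverage_alternatives:
            raise ValueError("at least one coverage alternative is required")


@dataclass
class FilterAudit:
    family_id: str
    size: int
    retained: bool
    reason: str  # "ok" | "focal" | "size" | "coverage"


def filter_families(families: Mapping[str, Sequence[str]],
                    taxa: TaxonMap,
                    rule: FamilyFilterRule = FamilyFilterRule(),
                    ) -> tuple[list[str], list[FilterAudit]]:
    """Apply the retention rule; returns retained family ids and a full
    audit (one record per family, stating the first failing clause)."""
    retained: list[str] = []
    audits: list[FilterAudit] = []
    for fam_id in sorted(families):
        members = families[fam_id]
        missing = taxa.unresolvable(members)
        if missing:
            raise KeyError(f"family {fam_id}: unresolvable sequence ids {missing}")
        group_hits: set[str] = set()
        for m in members:
            group_hits |= taxa.seq_groups(m)
        if rule.focal_group not in group_hits:
            rec = FilterAudit(fam_id, len(members), False, "focal")
        elif len(members) < rule.min_size:
            rec = FilterAudit(fam_id, len(members), False, "size")
        elif not any(alt <= group_hits for alt in rule.coverage_alternatives):
            rec = FilterAudit(fam_id, len(members), False, "coverage")
        else:
            rec = FilterAudit(fam_id, len(members), True, "ok")
            retained.append(fam_id)
        audits.append(rec)
    return retained, audits


def write_audit_tsv(path, audits: Sequence[FilterAudit]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["family_id", "size", "retained", "reason"])
        for a in audits:
            w.writerow([a.family_id, a.size, int(a.retained), a.reason])


# -- per-taxon copy structure ----------------------------------------------


def _monophyletic_unrooted(tree: PhyloTree, leafset: frozenset[str]) -> bool:
    """True iff ``leafset`` lies on one side of some edge (i.e. forms a
    clade in some rooting of the unrooted topology)."""
    all_leaves = frozenset(tree.leaf_labels)
    if len(leafset) in (1, len(all_leaves)):
        return True
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = frozenset(node.leaf_labels())
        if side == leafset or all_leaves - side == leafset:
            return True
    return False


def taxon_copy_profile(tree: PhyloTree, taxa: TaxonMap,
                       ) -> dict[str, tuple[int, bool]]:
    """Per-taxon (copy count, monophyly flag) for one gene tree.

    On a rooted tree a taxon is monophyletic iff its leaves are exactly
    the leaf set of one node; a single-copy taxon is monophyletic by
    convention.  On an unrooted tree monophyly means the taxon's leaves
    form one side of some edge.
    """
    by_taxon: dict[str, set[str]] = {}
    for leaf in tree.leaves():
        by_taxon.setdefault(taxa.taxon_of(leaf.label), set()).add(leaf.label)
    profile: dict[str, tuple[int, bool]] = {}
    for taxon, labels in sorted(by_taxon.items()):
        if len(labels) == 1:
            mono = True
        elif tree.rooted:
            mono = tree.lca(labels).leaf_labels() == labels
        else:
            mono = _monophyletic_unrooted(tree, frozenset(labels))
        profile[taxon] = (len(labels), mono)
    return profile


def select_representatives(tree: PhyloTree, taxa: TaxonMap,
                           ) -> dict[str, str] | None:
    """One sequence per taxon for the supermatrix track, or ``None`` if
    the family is rejected (some multi-copy taxon is not monophyletic).

    For a monophyletic multi-copy taxon the copy with the shortest
    terminal branch is chosen; ties break to the lexicographically
    smallest sequence id.  Terminal branch lengths must be present in
    that case.
    """
    profile = taxon_copy_profile(tree, taxa)
    by_taxon: dict[str, list] = {}
    for leaf in tree.leaves():
        by_taxon.setdefault(taxa.taxon_of(leaf.label), []).append(leaf)
    reps: dict[str, str] = {}
    for taxon, (count, mono) in profile.items():
        leaves = by_taxon[taxon]
        if count == 1:
            reps[taxon] = leaves[0].label
        elif mono:
            if any(l.length is None for l in leaves):
                raise RepresentativeError(
                    f"taxon {taxon}: multi-copy clade but terminal branch "
                    "lengths are missing")
            reps[taxon] = min(leaves, key=lambda l: (l.length, l.label)).label
        else:
            return None
    return reps


def write_representatives_tsv(path, rows: Iterable[tuple[str, str, str]]) -> None:
    """Rows: (family_id, taxon, sequence_id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["family_id", "taxon", "sequence_id"])
        for row in rows:
            w.writerow(row)
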