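"""Alignment gap masking, supermatrix concatenation with partitions,
per-taxon coverage accounting, and small assembly statistics.

Masking removes high-gap columns.  Two modes cover the two natural
readings of a 70% rule: ``inclusive`` drops a column whose gap fraction
is >= the threshold, ``strict`` only when it exceeds it; the supermatrix
track defaults to inclusive and the per-gene track to strict, both
configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MaskedAlignment",
    "SuperMatrix",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "mask_alignment",
    "concatenate",
    "assembly_stats",
]

DEFAULT_GAP_THRESHOLD = 0.7
GAP = "-"


@dataclass
class MaskedAlignment:
    ids: list[str]
    matrix: np.ndarray           # (rows, kept columns) of single chars
    kept_columns: list[int]      # original 0-based positions, increasing
    gap_fraction: np.ndarray     # per original column

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> str:
        return "".join(self.matrix[self.ids.index(seq_id)])

    def to_dict(self) -> dict[str, str]:
        return {i: "".join(r) for i, r in zip(self.ids, self.matrix)}


def read_fasta_alignment(path) -> dict[str, str]:
    recs = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not recs:
        raise ValueError(f"no sequences in {path}")
    return recs


def write_fasta_alignment(path, rows: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=i, description="") for i, s in rows.items()),
        str(path), "fasta")


def _to_matrix(aln: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(aln)
    lengths = {len(aln[i]) for i in ids}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    mat = np.array([list(aln[i]) for i in ids], dtype="<U1")
    return ids, mat


def mask_alignment(aln: Mapping[str, str],
                   threshold: float = DEFAULT_GAP_THRESHOLD,
                   mode: str = "inclusive",
                   gap_chars: str = GAP) -> MaskedAlignment:
    """Drop columns by gap fraction.

    ``inclusive``: drop when fraction >= threshold (e.g. a 10-row column
    with exactly 7 gaps goes at threshold 0.7); ``strict``: drop only
    when fraction > threshold (that same column stays).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ("inclusive", "strict"):
        raise ValueError("mode must be 'inclusive' or 'strict'")
    ids, mat = _to_matrix(aln)
    is_gap = np.isin(mat, list(gap_chars))
    frac = is_gap.mean(axis=0) if mat.size else np.zeros(mat.shape[1])
    drop = frac >= threshold if mode == "inclusive" else frac > threshold
    kept = np.flatnonzero(~drop)
    return MaskedAlignment(ids, mat[:, kept], [int(k) for k in kept], frac)


@dataclass
class SuperMatrix:
    taxa: list[str]
    matrix: np.ndarray                       # (taxa, total columns)
    partitions: dict[str, tuple[int, int]]   # gene -> [start, stop)
    coverage: dict[str, int] = field(default_factory=dict)  # taxon -> non-gap cols

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    # -- writers --------------------------------------------------------

    def write_phylip(self, path) -> None:
        """Relaxed PHYLIP (name, two spaces, full sequence)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {self.n_columns}\n")
            for taxon in self.taxa:
                fh.write(f"{taxon}  {self.row(taxon)}\n")

    def write_partitions(self, path, model: str = "WAG") -> None:
        """RAxML-style partition lines, 1-based inclusive coordinates."""
        with open(path, "w") as fh:
            for gene, (start, stop) in self.partitions.items():
                fh.write(f"{model}, {gene} = {start + 1}-{stop}\n")

    def write_coverage_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["taxon", "non_gap_columns"])
            for taxon in self.taxa:
                w.writerow([taxon, self.coverage[taxon]])


def concatenate(gene_blocks: Sequence[tuple[str, MaskedAlignment, Mapping[str, str]]],
                taxa: Sequence[str]) -> SuperMatrix:
    """Concatenate per-gene alignments into one taxon-by-column matrix.

    ``gene_blocks`` carries (gene id, masked alignment, row-id → taxon);
    genes are laid out left to right in input order, absent taxon×gene
    blocks are gap-filled, and per-taxon non-gap column counts (the
    coverage barplot data) are accumulated.
    """
    taxa = list(taxa)
    tpos = {t: i for i, t in enumerate(taxa)}
    total = sum(b[1].n_columns for b in gene_blocks)
    matrix = np.full((len(taxa), total), GAP, dtype="<U1")
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene_id, aln, row_taxon in gene_blocks:
        if gene_id in partitions:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen: set[str] = set()
        for r, seq_id in enumerate(aln.ids):
            taxon = row_taxon[seq_id]
            if taxon in seen:
                raise ValueError(
                    f"gene {gene_id}: two rows for taxon {taxon!r}")
            seen.add(taxon)
            if taxon not in tpos:
                raise ValueError(f"gene {gene_id}: unknown taxon {taxon!r}")
            matrix[tpos[taxon], offset:offset + aln.n_columns] = aln.matrix[r]
        partitions[gene_id] = (offset, offset + aln.n_columns)
        offset += aln.n_columns
    coverage = {t: int((matrix[i] != GAP).sum()) for i, t in enumerate(taxa)}
    return SuperMatrix(taxa, matrix, partitions, coverage)


def assembly_stats(lengths: Iterable[int], min_length: int = 400) -> dict:
    """Assembly summary with the N50 weighted-median statistic.

    N50 length is the largest L such that contigs of length >= L sum to
    at least half the total assembly; the N50 contig count is the number
    of contigs at least that long.  ``retained`` counts contigs passing
    the minimum-length cutoff (inclusive).
    """
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        raise ValueError("empty length list")
    if lengths[0] <= 0:
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    desc = lengths[::-1]
    cum = np.cumsum(desc)
    i = int(np.searchsorted(cum, total / 2))
    n50 = desc[i]
    n50_count = sum(1 for x in lengths if x >= n50)
    return {
        "total_length": total,
        "n_contigs": len(lengths),
        "retained": sum(1 for x in lengths if x >= min_length),
        "median": float(np.median(lengths)),
        "n50_length": n50,
        "n50_contig_count": n50_count,
    }
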