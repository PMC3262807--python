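"""Similarity-graph construction from BLAST-style hit tables and Markov
clustering (MCL) into gene families.

Edges are kept when the hit E-value passes the cutoff (default 1e-10),
reciprocal hits are merged keeping the best E-value, and the edge weight
is -log10(E) capped for E = 0.  Clustering follows the standard MCL
iteration — expansion (matrix power), inflation (entry-wise power with
column renormalisation), pruning — on a column-stochastic matrix with
self-loops; the default inflation of 5 produces the fine-grained
families this pipeline was designed around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FamilyAssignment",
    "build_similarity_graph",
    "read_hit_table",
    "mcl_cluster",
]

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_INFLATION = 5.0
DEFAULT_WEIGHT_CAP = 200.0


@dataclass
class FamilyAssignment:
    """A partition of sequence ids into families."""

    seq_to_family: dict[str, str]
    families: dict[str, list[str]]
    converged: bool = True

    def __post_init__(self):
        for fam, members in self.families.items():
            for m in members:
                assert self.seq_to_family[m] == fam

    @classmethod
    def from_clusters(cls, clusters: list[list[str]],
                      converged: bool = True) -> "FamilyAssignment":
        # family ids ordered by smallest member id, so numbering does not
        # depend on cluster discovery order
        clusters = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
        width = max(4, len(str(len(clusters))))
        families = {f"F{i + 1:0{width}d}": c for i, c in enumerate(clusters)}
        seq_to_family = {m: f for f, c in families.items() for m in c}
        return cls(seq_to_family, families, converged)

    def to_frame(self) -> pd.DataFrame:
        rows = [(seq, fam) for fam, members in sorted(self.families.items())
                for seq in members]
        return pd.DataFrame(rows, columns=["sequence_id", "family_id"])


def read_hit_table(path) -> pd.DataFrame:
    """Tab-separated hits: query, subject, evalue[, bitscore]; header
    optional (detected when the third field is not numeric)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    first = df.iloc[0]
    try:
        float(first[2])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["query", "subject", "evalue", "bitscore"][: df.shape[1]]
    df["evalue"] = df["evalue"].astype(float)
    return df


def build_similarity_graph(hits: pd.DataFrame,
                           evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                           weight_cap: float = DEFAULT_WEIGHT_CAP,
                           ) -> nx.Graph:
    """Undirected weighted graph from a hit table.

    A hit contributes an edge iff its E-value <= cutoff; A->B and B->A
    are merged keeping the smaller E-value; weight = -log10(E), capped
    at ``weight_cap`` (E-values of 0 take the cap).  Self-hits are
    dropped.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    required = {"query", "subject", "evalue"}
    if not required <= set(hits.columns):
        raise ValueError(f"hit table must have columns {sorted(required)}")
    g = nx.Graph()
    if hits.empty:
        warnings.warn("empty hit table: returning an empty graph")
        return g
    if (hits["evalue"] < 0).any():
        raise ValueError("negative E-values in hit table")
    kept = hits[hits["evalue"] <= evalue_cutoff]
    for q, s, e in kept[["query", "subject", "evalue"]].itertuples(index=False):
        if q == s:
            continue
        w = weight_cap if e == 0 else min(-np.log10(e), weight_cap)
        if g.has_edge(q, s):
            g[q][s]["weight"] = max(g[q][s]["weight"], w)
        else:
            g.add_edge(q, s, weight=w)
    # vertices that only appear in sub-cutoff hits still exist as singletons
    for col in ("query", "subject"):
        g.add_nodes_from(hits[col].unique())
    return g


def mcl_cluster(graph: nx.Graph,
                inflation: float = DEFAULT_INFLATION,
                expansion: int = 2,
                prune_threshold: float = 1e-5,
                max_iter: int = 200,
                tol: float = 1e-8,
                self_loop: str = "max-weight",
                ) -> FamilyAssignment:
    """Markov clustering of a similarity graph.

    Self-loops are set to each vertex's maximum incident edge weight
    (TribeMCL-style; ``self_loop='unit'`` uses 1), the matrix is made
    column-stochastic, and expansion/inflation/pruning iterate until the
    entry-wise change falls below ``tol`` or ``max_iter`` is reached (a
    warning flag on the result, not an error).  Clusters are the
    attractor systems; a vertex attracted to several systems goes to the
    one with the larger attraction, ties to the cluster whose smallest
    member id sorts first.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    if expansion < 2:
        raise ValueError("expansion must be at least 2")
    ids = sorted(graph.nodes)
    if not ids:
        return FamilyAssignment.from_clusters([])
    n = len(ids)
    pos = {v: i for i, v in enumerate(ids)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[pos[u], pos[v]] = M[pos[v], pos[u]] = w
    if self_loop == "max-weight":
        diag = M.max(axis=0)
        diag[diag == 0] = 1.0
    elif self_loop == "unit":
        diag = np.ones(n)
    else:
        raise ValueError("self_loop must be 'max-weight' or 'unit'")
    np.fill_diagonal(M, diag)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        last = M
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M /= M.sum(axis=0, keepdims=True)
        # prune the renormalised matrix, then restore column sums
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - last).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; "
                      "returning the current clustering")
    # attractors: vertices with positive diagonal mass; each attractor row
    # spans one (possibly shared) cluster
    attractors = np.flatnonzero(np.diag(M) > tol)
    if attractors.size == 0:  # pragma: no cover - self-loops prevent this
        attractors = np.arange(n)
    # merge attractor rows that overlap into attractor systems
    systems: list[set[int]] = []
    members_of: list[set[int]] = []
    for a in attractors:
        support = set(np.flatnonzero(M[a] > tol)) | {int(a)}
        merged = None
        for i, mem in enumerate(members_of):
            if mem & support:
                mem |= support
                systems[i].add(int(a))
                merged = i
                break
        if merged is None:
            systems.append({int(a)})
            members_of.append(support)
    # assign every vertex to the system with the largest attraction
    assignment: dict[int, int] = {}
    for v in range(n):
        best_sys, best_attr = None, 0.0
        for i, sysrows in enumerate(systems):
            attr = float(sum(M[a, v] for a in sysrows))
            better = attr > best_attr or (
                attr == best_attr and best_sys is not None and attr > 0
                and min(members_of[i]) < min(members_of[best_sys]))
            if better:
                best_sys, best_attr = i, attr
        if best_attr <= 0 or best_sys is None:
            assignment[v] = -v - 1  # isolated: its own singleton
        else:
            assignment[v] = best_sys
    clusters: dict[int, list[str]] = {}
    for v, s in assignment.items():
        clusters.setdefault(s, []).append(ids[v])
    return FamilyAssignment.from_clusters(list(clusters.values()), converged)
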