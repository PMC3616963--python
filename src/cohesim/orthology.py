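"""Homology graph, Markov clustering, and single-copy core extraction.

Gene ids carry their genome as ``genome|gene`` (the FASTA header
convention); the homology filter keeps a pair only if the shorter protein
is at least 60% of the longer one's length and the alignment covers at
least 80% of the shorter protein.  Clustering is Markov clustering (MCL)
on the symmetric bitscore-weighted graph with column normalization,
expansion (matrix squaring) and inflation (elementwise power) iterated to
a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SimilarityEdge", "GeneFamilyCluster", "filter_edges",
    "build_graph", "mcl_cluster", "extract_single_copy_core",
]


@dataclass
class SimilarityEdge:
    """One pairwise protein similarity hit (BLAST-style)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aligned_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class GeneFamilyCluster:
    members: List[str]                      # "genome|gene" ids
    per_genome_count: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster cannot be empty")
        if not self.per_genome_count:
            counts: Dict[str, int] = {}
            for m in self.members:
                genome = m.split("|", 1)[0]
                counts[genome] = counts.get(genome, 0) + 1
            self.per_genome_count = counts


def filter_edges(edges: Sequence[SimilarityEdge],
                 lengths: Mapping[str, int]) -> List[SimilarityEdge]:
    """Apply the length-ratio/coverage homology criterion.

    Keep an edge iff min(len)/max(len) >= 0.6 and the aligned span covers
    >= 80% of the shorter protein.  Reciprocal hits for the same pair are
    merged, keeping the best bitscore.
    """
    best: Dict[Tuple[str, str], SimilarityEdge] = {}
    for e in edges:
        for gid in (e.query_id, e.subject_id):
            if gid not in lengths:
                raise KeyError(f"unknown gene id in edges: {gid}")
        if e.query_id == e.subject_id:
            continue
        la, lb = lengths[e.query_id], lengths[e.subject_id]
        shorter, longer = min(la, lb), max(la, lb)
        if shorter / longer < 0.6:
            continue
        if e.aligned_len < 0.8 * shorter:
            continue
        key = tuple(sorted((e.query_id, e.subject_id)))
        if key not in best or e.bitscore > best[key].bitscore:
            best[key] = e
    return [best[k] for k in sorted(best)]


def build_graph(edges: Sequence[SimilarityEdge],
                nodes: Optional[Sequence[str]] = None
                ) -> Tuple[List[str], np.ndarray]:
    """Symmetric weighted adjacency (bitscore weights) over sorted node ids."""
    ids = set(nodes) if nodes is not None else set()
    for e in edges:
        ids.add(e.query_id)
        ids.add(e.subject_id)
    order = sorted(ids)
    idx = {g: i for i, g in enumerate(order)}
    adj = np.zeros((len(order), len(order)))
    for e in edges:
        i, j = idx[e.query_id], idx[e.subject_id]
        w = max(e.bitscore, 0.0)
        adj[i, j] = max(adj[i, j], w)
        adj[j, i] = adj[i, j]
    np.fill_diagonal(adj, 0.0)
    return order, adj


class MCLNotConverged(RuntimeError):
    def __init__(self, clusters: List["GeneFamilyCluster"]):
        super().__init__("MCL did not converge; partial result attached")
        self.clusters = clusters


def mcl_cluster(node_ids: Sequence[str], adjacency: np.ndarray,
                inflation: float = 1.5, max_iter: int = 200,
                tol: float = 1e-6,
                strict: bool = False) -> List[GeneFamilyCluster]:
    """Markov clustering of a weighted homology graph.

    Self-loops are added as the column maximum (standard MCL practice) so
    singletons are stable, columns are normalized to stochastic, and
    expansion/inflation is iterated until the matrix change drops below
    ``tol``.  Clusters are the connected components of the attractor
    matrix; every node lands in exactly one cluster.  If the iteration has
    not converged after ``max_iter`` rounds the partial clustering is
    flagged: a warning is emitted, or ``MCLNotConverged`` (carrying the
    partial result) is raised when ``strict``.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    n = len(node_ids)
    if adjacency.shape != (n, n):
        raise ValueError("adjacency shape does not match node list")
    m = np.array(adjacency, dtype=float)
    np.fill_diagonal(m, 0.0)
    loop = m.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    clusters = _components(node_ids, m > 1e-8)
    if not converged:
        if strict:
            raise MCLNotConverged(clusters)
        import warnings

        warnings.warn("MCL did not converge; returning partial clustering",
                      RuntimeWarning, stacklevel=2)
    return clusters


def _components(node_ids: Sequence[str], mask: np.ndarray
                ) -> List[GeneFamilyCluster]:
    n = len(node_ids)
    sym = mask | mask.T
    seen = np.zeros(n, dtype=bool)
    comps: List[List[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.nonzero(sym[v])[0]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        comps.append(comp)
    out = []
    for comp in comps:
        members = sorted(node_ids[i] for i in comp)
        out.append(GeneFamilyCluster(members))
    return sorted(out, key=lambda c: c.members[0])


def extract_single_copy_core(clusters: Sequence[GeneFamilyCluster],
                             genomes: Sequence[str]) -> List[GeneFamilyCluster]:
    """Clusters with exactly one member in every genome, in stable order."""
    want = set(genomes)
    out = [c for c in clusters
           if set(c.per_genome_count) == want
           and all(v == 1 for v in c.per_genome_count.values())]
    return sorted(out, key=lambda c: c.members[0])
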