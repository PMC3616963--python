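"""File formats: FASTA, newick, 12-column tabular hits, posterior tracks.

FASTA headers follow the ``genome|gene_id`` convention.  The hits table is
the classic 12-column tabular dialect (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore).  Posterior
tracks are TSV with a ``site  S  R`` header.  Malformed records fail with
the offending line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .orthology import GeneFamilyCluster, SimilarityEdge
from .recomb import PosteriorTrack
from .trees import Tree, parse_newick

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Ordered mapping of record id -> sequence (CRLF and wrapping safe)."""
    from Bio import SeqIO

    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path: PathLike, seqs: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_newick(path: PathLike) -> Tree:
    return parse_newick(Path(path).read_text())


def write_newick(path: PathLike, tree: Tree, support: bool = True) -> None:
    Path(path).write_text(tree.newick(support=support) + "\n")


def read_hits_tsv(path: PathLike) -> List[SimilarityEdge]:
    """Parse 12-column tabular homology hits."""
    edges: List[SimilarityEdge] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                edges.append(SimilarityEdge(
                    query_id=parts[0], subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aligned_len=int(parts[3]),
                    evalue=float(parts[10]), bitscore=float(parts[11])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return edges


def write_hits_tsv(path: PathLike, edges: Sequence[SimilarityEdge]) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write("\t".join(map(str, [
                e.query_id, e.subject_id, f"{e.pct_identity:.2f}",
                e.aligned_len, 0, 0, 0, 0, 0, 0,
                f"{e.evalue:.3g}", f"{e.bitscore:.1f}"])) + "\n")


def read_track_tsv(path: PathLike) -> PosteriorTrack:
    """Read a per-site posterior track (site, S, R) with a header line."""
    s_vals: List[float] = []
    r_vals: List[float] = []
    with open(path) as fh:
        header = fh.readline().strip().lower().split("\t")
        if header[:3] != ["site", "s", "r"]:
            raise ValueError(f"{path}:1: expected header 'site\\tS\\tR'")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                s_vals.append(float(parts[1]))
                r_vals.append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return PosteriorTrack(np.array(s_vals), np.array(r_vals))


def write_track_tsv(path: PathLike, track: PosteriorTrack) -> None:
    with open(path, "w") as fh:
        fh.write("site\tS\tR\n")
        for i, (s, r) in enumerate(zip(track.S, track.R), start=1):
            fh.write(f"{i}\t{s:.6g}\t{r:.6g}\n")


def write_clusters_tsv(path: PathLike,
                       clusters: Sequence[GeneFamilyCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenome\tgene_id\n")
        for k, c in enumerate(clusters):
            for m in c.members:
                genome, gene = m.split("|", 1)
                fh.write(f"cluster{k:05d}\t{genome}\t{gene}\n")


def read_clusters_tsv(path: PathLike) -> List[Tuple[str, GeneFamilyCluster]]:
    rows: Dict[str, List[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("cluster_id"):
            raise ValueError(f"{path}:1: missing cluster table header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            rows.setdefault(parts[0], []).append(f"{parts[1]}|{parts[2]}")
    return [(cid, GeneFamilyCluster(sorted(members)))
            for cid, members in sorted(rows.items())]


def write_truth_log_tsv(path: PathLike, rows: Sequence[Tuple]) -> None:
    """Tract truth log: (gene_id, donor, recipient, start, end, type)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tdonor\trecipient\tstart\tend\ttype\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")
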