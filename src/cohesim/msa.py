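"""Protein alignment, back-translation to codons, and gap-column pruning.

Pairwise alignment is affine-gap global alignment (Needleman-Wunsch /
Gotoh; the first residue of a gap costs ``gap_open``, each further residue
``gap_extend``), delegated to Bio.Align.PairwiseAligner.  The progressive
multiple aligner is a small self-contained implementation (k-mer distance
guide tree built by neighbor joining, profile-profile merges in postorder)
intended for families of up to ~10 closely related sequences; externally
produced alignments can be imported as FASTA instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"


@dataclass
class ProteinAlignment:
    names: List[str]
    seqs: List[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


@dataclass
class CodonAlignment:
    names: List[str]
    seqs: List[str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.seqs}
        if len(lens) > 1:
            raise ValueError("aligned rows must have equal length")
        if self.seqs and len(self.seqs[0]) % 3 != 0:
            raise ValueError("codon alignment length must be divisible by 3")
        for name, s in zip(self.names, self.seqs):
            for k in range(0, len(s), 3):
                cod = s[k: k + 3]
                if GAP in cod and cod != "---":
                    raise ValueError(
                        f"gaps must occur in whole codons ({name} at {k+1})")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def pairwise_align(a: str, b: str, matrix=None,
                   gap_open: float = -11.0, gap_extend: float = -1.0):
    """Global affine-gap alignment of two protein sequences.

    Returns (aligned_a, aligned_b, score, pct_identity,
    aligned_fraction_of_shorter).  Percent identity is over columns where
    both rows have a residue; aligned_fraction is the count of such columns
    divided by the length of the shorter input.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix if matrix is not None else _blosum62()
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    both = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
    ident = sum(x == y for x, y in both)
    pct = 100.0 * ident / len(both) if both else 0.0
    frac = len(both) / min(len(a), len(b))
    return ra, rb, float(aln.score), pct, frac


# -- progressive MSA --------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i: i + k] for i in range(len(a) - k + 1)}
    kb = {b[i: i + k] for i in range(len(b) - k + 1)}
    denom = min(len(ka), len(kb))
    return 1.0 - len(ka & kb) / denom if denom else 1.0


def _nj_join_order(dist: np.ndarray, names: List[str]) -> List[Tuple[int, int]]:
    """Neighbor-joining join order over item indices (0..n-1 are inputs,
    joins create new indices).  Ties broken lexicographically by the sorted
    name tuples of the candidate pair, so the result is independent of
    input order."""
    active = list(range(len(names)))
    d = {(i, j): float(dist[i, j]) for i in range(len(names))
         for j in range(len(names)) if i < j}
    tag = {i: (names[i],) for i in range(len(names))}
    joins: List[Tuple[int, int]] = []
    nxt = len(names)
    while len(active) > 2:
        n = len(active)
        totals = {i: sum(d[tuple(sorted((i, j)))] for j in active if j != i)
                  for i in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = active[ii], active[jj]
                q = (n - 2) * d[tuple(sorted((i, j)))] - totals[i] - totals[j]
                key = (q, tuple(sorted(tag[i] + tag[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        joins.append((i, j))
        tag[nxt] = tuple(sorted(tag[i] + tag[j]))
        for k in active:
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[tuple(sorted((nxt, k)))] = 0.5 * (dik + djk)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    if len(active) == 2:
        joins.append((active[0], active[1]))
    return joins


_AA_INDEX = {c: i for i, c in enumerate(AA)}


def _profile(rows: List[str]) -> np.ndarray:
    """(n_columns, 21) residue frequency profile; column 20 is the gap."""
    n = len(rows[0])
    prof = np.zeros((n, 21))
    for r in rows:
        for i, c in enumerate(r):
            prof[i, _AA_INDEX.get(c, 20) if c != GAP else 20] += 1
    return prof / len(rows)


def _profile_scores(pa: np.ndarray, pb: np.ndarray, S: np.ndarray) -> np.ndarray:
    ra, rb = pa[:, :20], pb[:, :20]
    wa = ra.sum(axis=1, keepdims=True)
    wb = rb.sum(axis=1, keepdims=True)
    na = np.divide(ra, wa, out=np.zeros_like(ra), where=wa > 0)
    nb = np.divide(rb, wb, out=np.zeros_like(rb), where=wb > 0)
    return (na @ S @ nb.T) * (wa * wb.T)


def _gotoh_merge(rows_a: List[str], rows_b: List[str], S: np.ndarray,
                 gap_open: float, gap_extend: float) -> Tuple[List[str], List[str]]:
    """Affine-gap profile-profile alignment; returns gapped row sets."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    sc = _profile_scores(pa, pb, S)
    n, m = sc.shape
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)   # gap in B (vertical)
    Y = np.full((n + 1, m + 1), neg)   # gap in A (horizontal)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        ptrX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        ptrY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc[i - 1, j - 1]
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + s
            ptrM[i, j] = k
            ox = (M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            k = int(np.argmax(ox))
            X[i, j] = ox[k]
            ptrX[i, j] = 0 if k == 0 else 1
            oy = (M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
            k = int(np.argmax(oy))
            Y[i, j] = oy[k]
            ptrY[i, j] = 0 if k == 0 else 2
    state = int(np.argmax((M[n, m], X[n, m], Y[n, m])))
    i, j = n, m
    ops: List[int] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = ptrM[i, j]
            ops.append(0)
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            prev = ptrX[i, j]
            ops.append(1)
            i -= 1
            state = prev
        else:
            prev = ptrY[i, j]
            ops.append(2)
            j -= 1
            state = prev
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in (0, 2):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def progressive_msa(seqs: Sequence[Tuple[str, str]],
                    gap_open: float = -11.0,
                    gap_extend: float = -1.0) -> ProteinAlignment:
    """Progressive multiple alignment of protein sequences.

    Guide tree from k-mer distances + neighbor joining; profiles merged in
    postorder.  Deterministic: all ties break on sorted name tuples.
    """
    items = sorted(seqs, key=lambda x: x[0])
    if not items:
        raise ValueError("no sequences")
    if len(items) == 1:
        return ProteinAlignment([items[0][0]], [items[0][1]])
    names = [n for n, _ in items]
    n = len(items)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(items[i][1], items[j][1])
    S = np.array([[_blosum62()[a][b] for b in AA] for a in AA], dtype=float)
    groups: Dict[int, Tuple[List[str], List[str]]] = {
        i: ([items[i][0]], [items[i][1]]) for i in range(n)}
    nxt = n
    for i, j in _nj_join_order(dist, names):
        na_, ra = groups.pop(i)
        nb_, rb = groups.pop(j)
        ga, gb = _gotoh_merge(ra, rb, S, gap_open, gap_extend)
        groups[nxt] = (na_ + nb_, ga + gb)
        nxt += 1
    (_, (out_names, out_rows)), = groups.items()
    order = sorted(range(len(out_names)), key=lambda k: out_names[k])
    return ProteinAlignment([out_names[k] for k in order],
                            [out_rows[k] for k in order])


# -- back-translation and pruning -------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def backtranslate(p: ProteinAlignment, cds: Dict[str, str]) -> CodonAlignment:
    """Replace each aligned amino acid by its source codon; gaps -> '---'.

    A terminal stop codon on the CDS is tolerated and dropped.  Length
    mismatches and internal stop codons are rejected naming the member.
    """
    out: List[str] = []
    for name, row in zip(p.names, p.seqs):
        if name not in cds:
            raise ValueError(f"no CDS for {name}")
        nt = cds[name].upper()
        if len(nt) % 3 == 0 and nt[-3:] in _STOPS:
            nt = nt[:-3]
        n_aa = sum(1 for c in row if c != GAP)
        if len(nt) != 3 * n_aa:
            raise ValueError(
                f"CDS length mismatch for {name}: {len(nt)} nt vs "
                f"{n_aa} residues")
        for k in range(0, len(nt), 3):
            if nt[k: k + 3] in _STOPS:
                raise ValueError(f"internal stop codon in {name} at nt {k+1}")
        codons = iter(nt[k: k + 3] for k in range(0, len(nt), 3))
        out.append("".join(next(codons) if c != GAP else "---" for c in row))
    return CodonAlignment(list(p.names), out)


def prune_gap_columns(aln, threshold: float = 0.5):
    """Drop columns whose gap fraction is >= threshold (inclusive).

    For codon alignments the unit is the codon column ('---' counts as the
    gap state), which keeps the reading frame intact.  Column order is
    preserved; the operation is idempotent.
    """
    if isinstance(aln, CodonAlignment):
        width = 3
        cls = CodonAlignment
    else:
        width = 1
        cls = ProteinAlignment
    if not aln.seqs:
        return cls(list(aln.names), list(aln.seqs))
    ncol = len(aln.seqs[0]) // width
    nrow = len(aln.seqs)
    keep = []
    for c in range(ncol):
        gaps = sum(1 for s in aln.seqs
                   if s[c * width: (c + 1) * width] == GAP * width)
        if gaps / nrow < threshold:
            keep.append(c)
    rows = ["".join(s[c * width: (c + 1) * width] for c in keep)
            for s in aln.seqs]
    return cls(list(aln.names), rows)
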