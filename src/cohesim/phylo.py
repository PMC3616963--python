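"""Maximum-likelihood gene trees for small taxon sets under GTR+Gamma.

The likelihood is Felsenstein pruning over compressed site patterns with
discrete-Gamma rate averaging; gaps and ambiguity codes are treated as
(partial) missing data.  Because the target analyses involve at most 8
taxa, tree search is exhaustive over all (2n-5)!! unrooted topologies
rather than heuristic: every topology gets least-squares initial branch
lengths, and the leading candidates (or all, in thorough mode) are refined
by per-branch Brent coordinate ascent.

The hot loop is JIT-compiled with numba; everything else is numpy/scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.optimize import minimize, minimize_scalar

from .gtr import GTRParams, eigendecompose, transition_matrices
from .trees import (Tree, cluster_trees, enumerate_topologies,
                    n_unrooted_topologies, weighted_rf)

__all__ = [
    "GTRParams", "encode_alignment", "log_likelihood", "fit_tree",
    "exhaustive_ml_search", "SearchResult", "bootstrap_support",
    "weighted_rf", "cluster_trees", "topology_census", "CensusResult",
]

MIN_BLEN = 1e-8
MAX_BLEN = 5.0

# IUPAC nucleotide codes -> per-state indicator rows of the tip table
_CODES = "ACGTRYSWKMBDHVN-"
_CODE_STATES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT",
}
TIP_TABLE = np.zeros((len(_CODES), 4))
for _i, _c in enumerate(_CODES):
    for _s in _CODE_STATES[_c]:
        TIP_TABLE[_i, "ACGT".index(_s)] = 1.0
_CODE_INDEX = {c: i for i, c in enumerate(_CODES)}
_CODE_INDEX["U"] = _CODE_INDEX["T"]


def encode_alignment(seqs: Mapping[str, str]) -> Tuple[List[str], np.ndarray]:
    """Encode label->sequence into (sorted labels, code matrix)."""
    labels = sorted(seqs)
    if not labels:
        raise ValueError("empty alignment")
    lens = {len(seqs[lab]) for lab in labels}
    if len(lens) != 1:
        raise ValueError("rows must have equal length")
    mat = np.empty((len(labels), lens.pop()), dtype=np.uint8)
    for r, lab in enumerate(labels):
        for c, ch in enumerate(seqs[lab].upper()):
            try:
                mat[r, c] = _CODE_INDEX[ch]
            except KeyError:
                raise ValueError(f"bad character {ch!r} in {lab}") from None
    return labels, mat


def _compress(mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return np.ascontiguousarray(patterns), counts.astype(np.float64)


@njit(cache=True)
def _prune_kernel(order, parent, leaf_row, patterns, counts, P, tiptab, pi):
    n_nodes = parent.shape[0]
    ncat = P.shape[1]
    npat = patterns.shape[1]
    L = np.empty((n_nodes, 4))
    root = order[-1]
    total = 0.0
    for p in range(npat):
        site = 0.0
        for c in range(ncat):
            for k in range(order.shape[0]):
                node = order[k]
                row = leaf_row[node]
                if row >= 0:
                    code = patterns[row, p]
                    for x in range(4):
                        L[node, x] = tiptab[code, x]
                else:
                    for x in range(4):
                        L[node, x] = 1.0
            for k in range(order.shape[0]):
                node = order[k]
                if node == root:
                    continue
                par = parent[node]
                for x in range(4):
                    m = 0.0
                    for y in range(4):
                        m += P[node, c, x, y] * L[node, y]
                    L[par, x] *= m
            cat_lik = 0.0
            for x in range(4):
                cat_lik += pi[x] * L[root, x]
            site += cat_lik
        site /= ncat
        if site < 1e-300:
            site = 1e-300
        total += counts[p] * np.log(site)
    return total


class _LikelihoodEngine:
    """Caches the alignment encoding and model spectra for one gene."""

    def __init__(self, seqs: Mapping[str, str], params: GTRParams):
        self.labels, mat = encode_alignment(seqs)
        self.patterns, self.counts = _compress(mat)
        self.n_sites = mat.shape[1]
        self.set_params(params)

    def set_params(self, params: GTRParams) -> None:
        self.params = params
        self.lam, self.u, self.v = eigendecompose(params)
        self.rates = params.rate_categories()
        self.pi = params.base_freqs

    def _encode_tree(self, tree: Tree):
        if sorted(tree.leaf_labels()) != self.labels:
            raise ValueError("tree leaves do not match alignment rows")
        order = np.array(tree.postorder(), dtype=np.int64)
        parent = np.array(tree.parent, dtype=np.int64)
        leaf_row = np.full(tree.n_nodes(), -1, dtype=np.int64)
        for i, lab in enumerate(self.labels):
            leaf_row[tree.find_leaf(lab)] = i
        return order, parent, leaf_row

    def loglik(self, tree: Tree,
               lengths: Optional[np.ndarray] = None) -> float:
        order, parent, leaf_row = self._encode_tree(tree)
        blen = (np.array(tree.length, dtype=float)
                if lengths is None else lengths)
        P = transition_matrices(self.lam, self.u, self.v, blen, self.rates)
        return float(_prune_kernel(order, parent, leaf_row, self.patterns,
                                   self.counts, P, TIP_TABLE, self.pi))

    def optimize_branches(self, tree: Tree, sweeps: int = 3,
                          tol: float = 1e-6, xatol: float = 1e-6) -> float:
        order, parent, leaf_row = self._encode_tree(tree)
        blen = np.array(tree.length, dtype=float)
        np.clip(blen, MIN_BLEN, MAX_BLEN, out=blen)

        def eval_lengths(b):
            P = transition_matrices(self.lam, self.u, self.v, b, self.rates)
            return float(_prune_kernel(order, parent, leaf_row, self.patterns,
                                       self.counts, P, TIP_TABLE, self.pi))

        cur = eval_lengths(blen)
        nodes = [n for n in tree.postorder() if n != tree.root]
        for _ in range(sweeps):
            before = cur
            for node in nodes:
                def neg(t, node=node):
                    b = blen.copy()
                    b[node] = t
                    return -eval_lengths(b)

                res = minimize_scalar(neg, bounds=(MIN_BLEN, MAX_BLEN),
                                      method="bounded",
                                      options={"xatol": xatol, "maxiter": 40})
                cand_x, cand_ll = float(res.x), -res.fun
                # Brent can miss a boundary optimum on a flat surface:
                # collapse to the minimum length when it is at least as good
                ll_floor = -neg(MIN_BLEN)
                if ll_floor >= cand_ll - 1e-9:
                    cand_x, cand_ll = MIN_BLEN, ll_floor
                if cand_ll > cur:
                    blen[node] = cand_x
                    cur = cand_ll
            if cur - before < tol:
                break
        for node, b in enumerate(blen):
            tree.length[node] = float(b)
        return cur


def log_likelihood(seqs: Mapping[str, str], tree: Tree,
                   params: GTRParams) -> float:
    """Log-likelihood of an alignment on a tree under GTR(+Gamma).

    Gamma categories are averaged with equal weights; gaps/N are missing
    data (all-ones tip partials).
    """
    return _LikelihoodEngine(seqs, params).loglik(tree)


def _check_informative_rows(seqs: Mapping[str, str]) -> None:
    for lab, s in seqs.items():
        if all(c in "-Nn" for c in s):
            raise ValueError(f"row {lab} is entirely missing data")


def empirical_params(seqs: Mapping[str, str],
                     gamma_shape: Optional[float] = 1.0) -> GTRParams:
    """Starting model: empirical base frequencies, unit exchangeabilities."""
    counts = np.ones(4)
    for s in seqs.values():
        for ch in s.upper():
            i = "ACGT".find(ch)
            if i >= 0:
                counts[i] += 1
    return GTRParams(np.ones(6), counts / counts.sum(), gamma_shape)


def fit_tree(seqs: Mapping[str, str], tree: Tree, p0: GTRParams,
             optimize_model: bool = True, tol: float = 1e-6,
             max_rounds: int = 4) -> Tuple[Tree, GTRParams, float]:
    """Optimize branch lengths (and optionally model parameters) on a fixed
    topology by coordinate ascent; the returned log-likelihood never falls
    below the starting value."""
    _check_informative_rows(seqs)
    eng = _LikelihoodEngine(seqs, p0)
    t = tree.copy()
    cur = eng.optimize_branches(t, sweeps=3, tol=tol)
    params = p0
    if optimize_model:
        for _ in range(max_rounds):
            before = cur
            params = _optimize_model(eng, t, params)
            eng.set_params(params)
            cur = max(cur, eng.loglik(t))
            cur = max(cur, eng.optimize_branches(t, sweeps=2, tol=tol))
            if cur - before < tol:
                break
    return t, params, cur


def _optimize_model(eng: "_LikelihoodEngine", tree: Tree,
                    params: GTRParams) -> GTRParams:
    """One round of exchangeability (+ gamma shape) optimization."""
    base = params.base_freqs
    shape0 = params.gamma_shape

    def unpack(x):
        ex = np.ones(6)
        ex[:5] = np.exp(x[:5])
        shape = (np.exp(x[5]) if shape0 is not None and len(x) > 5
                 else shape0)
        return GTRParams(ex, base, shape)

    x0 = np.zeros(6)
    x0[:5] = np.log(np.maximum(params.exchangeabilities[:5]
                               / params.exchangeabilities[5], 1e-6))
    if shape0 is not None:
        x0[5] = np.log(shape0)

    def neg(x):
        try:
            eng.set_params(unpack(x))
        except ValueError:
            return 1e12
        return -eng.loglik(tree)

    nfree = 6 if shape0 is not None else 5
    res = minimize(neg, x0[:nfree].copy() if nfree == 5 else x0,
                   method="L-BFGS-B",
                   bounds=[(-7, 7)] * nfree,
                   options={"maxiter": 40, "ftol": 1e-8})
    x = np.zeros(6)
    x[:nfree] = res.x
    out = unpack(x)
    eng.set_params(out)
    return out


# -- distances and least-squares branch lengths -----------------------------

def jc_distance_matrix(seqs: Mapping[str, str]) -> Tuple[List[str], np.ndarray]:
    """Jukes-Cantor corrected pairwise distances with pairwise deletion."""
    labels, mat = encode_alignment(seqs)
    good = mat < 4          # unambiguous states only
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            use = good[i] & good[j]
            tot = int(use.sum())
            p = (np.count_nonzero(mat[i, use] != mat[j, use]) / tot
                 if tot else 0.0)
            arg = 1.0 - 4.0 * p / 3.0
            d[i, j] = d[j, i] = (-0.75 * np.log(arg) if arg > 0.05 else 2.5)
    return labels, d


def _path_matrix(tree: Tree, labels: List[str]) -> Tuple[np.ndarray, List[int]]:
    """Pair x edge incidence matrix for least-squares branch lengths."""
    sets = tree.clade_leafsets()
    nodes = [n for n in range(tree.n_nodes()) if n != tree.root]
    idx = {lab: i for i, lab in enumerate(labels)}
    pairs = [(i, j) for i in range(len(labels))
             for j in range(i + 1, len(labels))]
    A = np.zeros((len(pairs), len(nodes)))
    for e, node in enumerate(nodes):
        side = {idx[lab] for lab in sets[node]}
        for r, (i, j) in enumerate(pairs):
            if (i in side) != (j in side):
                A[r, e] = 1.0
    return A, nodes


def ls_branch_lengths(tree: Tree, labels: List[str], dmat: np.ndarray,
                      pinv: Optional[np.ndarray] = None,
                      nodes: Optional[List[int]] = None) -> None:
    """Set branch lengths from the distance matrix by least squares."""
    if pinv is None or nodes is None:
        A, nodes = _path_matrix(tree, labels)
        pinv = np.linalg.pinv(A)
    iu = np.triu_indices(len(labels), k=1)
    lengths = pinv @ dmat[iu]
    for node, b in zip(nodes, lengths):
        tree.length[node] = float(max(b, MIN_BLEN))


# -- exhaustive search ------------------------------------------------------

@dataclass
class SearchResult:
    best: Tree
    table: List[Tuple[str, float]]       # (topology splits key, logL)
    tie: bool = False
    n_topologies: int = 0


def exhaustive_ml_search(seqs: Mapping[str, str],
                         p0: Optional[GTRParams] = None,
                         refine_top: Optional[int] = None,
                         sweeps: int = 3,
                         xatol: float = 1e-6) -> SearchResult:
    """Exhaustive ML topology search for 4..8 taxa.

    Every unrooted topology is scored with least-squares branch lengths;
    ``refine_top`` topologies (all when None) are then refined by Brent
    coordinate ascent.  The argmax is returned, ties broken by canonical
    topology string order and flagged.
    """
    labels = sorted(seqs)
    n = len(labels)
    if not 4 <= n <= 8:
        raise ValueError("exhaustive search supports 4..8 taxa")
    _check_informative_rows(seqs)
    if p0 is None:
        p0 = empirical_params(seqs)
    eng = _LikelihoodEngine(seqs, p0)
    _, dmat = jc_distance_matrix(seqs)
    topologies = enumerate_topologies(labels)
    assert len(topologies) == n_unrooted_topologies(n)
    scored: List[Tuple[float, int]] = []
    for k, t in enumerate(topologies):
        A, nodes = _path_matrix(t, labels)
        ls_branch_lengths(t, labels, dmat, np.linalg.pinv(A), nodes)
        scored.append((eng.loglik(t), k))
    scored.sort(key=lambda x: (-x[0], topologies[x[1]].topology_key()))
    n_refine = len(topologies) if refine_top is None else min(
        refine_top, len(topologies))
    refined: List[Tuple[float, int]] = []
    for logl, k in scored[:n_refine]:
        t = topologies[k]
        ll = eng.optimize_branches(t, sweeps=sweeps, xatol=xatol)
        refined.append((ll, k))
    refined += scored[n_refine:]
    refined.sort(key=lambda x: (-x[0], topologies[x[1]].topology_key()))
    best_ll, best_k = refined[0]
    tie = len(refined) > 1 and abs(refined[1][0] - best_ll) < 1e-9
    table = [(topologies[k].topology_key(), ll) for ll, k in refined]
    return SearchResult(best=topologies[best_k], table=table, tie=tie,
                        n_topologies=len(topologies))


def bootstrap_support(seqs: Mapping[str, str], best: Tree,
                      n_reps: int = 100, seed: int = 0,
                      p0: Optional[GTRParams] = None,
                      refine_top: int = 1) -> Tree:
    """Site-resampling bootstrap; support = % of replicate searches whose
    best tree contains each internal bipartition of ``best``.

    An alignment with no variable sites is flagged unresolved by setting
    every internal support to 0.
    """
    labels = sorted(seqs)
    n_sites = len(seqs[labels[0]])
    out = best.copy()
    sets = out.clade_leafsets()
    all_labels = frozenset(labels)
    internal = [n for n in range(out.n_nodes())
                if n != out.root and out.label[n] is None
                and 2 <= len(sets[n]) <= len(labels) - 2]
    arr = {lab: np.frombuffer(seqs[lab].encode(), dtype=np.uint8)
           for lab in labels}
    variable = False
    stack = np.stack([arr[lab] for lab in labels])
    variable = bool((stack != stack[0]).any())
    if not variable:
        for node in internal:
            out.support[node] = 0.0
        return out
    rng = np.random.default_rng(seed)
    hits = {node: 0 for node in internal}
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = {lab: arr[lab][cols].tobytes().decode() for lab in labels}
        res = exhaustive_ml_search(rep, p0=p0, refine_top=refine_top,
                                   sweeps=1, xatol=1e-4)
        rep_splits = set(res.best.bipartitions())
        for node in internal:
            side = sets[node]
            key = (frozenset(all_labels - side) if min(all_labels) in side
                   else side)
            if key in rep_splits:
                hits[node] += 1
    for node in internal:
        out.support[node] = 100.0 * hits[node] / n_reps
    return out


# -- topology census --------------------------------------------------------

@dataclass
class CensusResult:
    """9-class census of split-respecting trees plus the incongruent rest.

    ``counts`` is keyed by (within_A_pair, within_B_pair) with each pair
    rendered as "x+y" in sorted order.  ``n_filtered_out`` counts trees
    dropped by the support floor (only when a floor is set).
    """

    counts: Dict[Tuple[str, str], int]
    incongruent: int
    n_total: int
    n_considered: int
    n_filtered_out: int
    assignments: List[Optional[Tuple[str, str]]] = field(default_factory=list)

    def split_respecting(self) -> int:
        return sum(self.counts.values())


def _pair_key(a: str, b: str) -> str:
    return "+".join(sorted((a, b)))


def _within_resolution(tree: Tree, group: Sequence[str]) -> Optional[str]:
    members = sorted(group)
    pairs = [(members[0], members[1]), (members[0], members[2]),
             (members[1], members[2])]
    found = [p for p in pairs if tree.has_split(p)]
    if len(found) != 1:
        return None
    return _pair_key(*found[0])


def topology_census(trees: Sequence[Tree], group_A: Sequence[str],
                    group_B: Sequence[str],
                    support_floor: Optional[float] = None) -> CensusResult:
    """Classify each gene tree by the deep A|B split and the within-group
    resolutions.

    A tree respects the split iff the A|B bipartition is present; its class
    is then the pair of within-group cherries.  With a support floor, only
    trees whose internal supports are ALL strictly above the floor are
    counted.  Polytomies (missing within-group resolution) are counted as
    incongruent.
    """
    group_A = sorted(group_A)
    group_B = sorted(group_B)
    if len(group_A) != 3 or len(group_B) != 3:
        raise ValueError("census requires two groups of exactly 3 taxa")
    want = set(group_A) | set(group_B)
    counts: Dict[Tuple[str, str], int] = {}
    for pa in [(0, 1), (0, 2), (1, 2)]:
        for pb in [(0, 1), (0, 2), (1, 2)]:
            key = (_pair_key(group_A[pa[0]], group_A[pa[1]]),
                   _pair_key(group_B[pb[0]], group_B[pb[1]]))
            counts[key] = 0
    incongruent = 0
    filtered_out = 0
    assignments: List[Optional[Tuple[str, str]]] = []
    for t in trees:
        if set(t.leaf_labels()) != want:
            raise ValueError("tree leaves must be exactly A ∪ B")
        if support_floor is not None:
            sup = [s for s in t.split_supports().values()]
            if any(s is None or s <= support_floor for s in sup):
                filtered_out += 1
                assignments.append(None)
                continue
        if not t.has_split(group_A):
            incongruent += 1
            assignments.append(None)
            continue
        ra = _within_resolution(t, group_A)
        rb = _within_resolution(t, group_B)
        if ra is None or rb is None:
            incongruent += 1
            assignments.append(None)
            continue
        counts[(ra, rb)] += 1
        assignments.append((ra, rb))
    n_considered = len(trees) - filtered_out
    return CensusResult(counts=counts, incongruent=incongruent,
                        n_total=len(trees), n_considered=n_considered,
                        n_filtered_out=filtered_out,
                        assignments=assignments)
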