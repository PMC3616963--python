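"""Intragenic recombination detectors and r/m post-processing.

Four detectors over one gene alignment:

* Phi — mean pairwise incompatibility of nearby informative sites,
  permutation-tested against site-order shuffles (small observed values of
  the statistic indicate recombination);
* NSS — neighbour similarity score: the fraction of adjacent informative
  site pairs that are compatible (large values indicate recombination);
* MaxChi — maximum 2x2 chi-square of (mismatch/match) x (left/right of a
  sliding breakpoint) over all sequence pairs;
* gene-conversion fragments — maximal scoring runs of matching polymorphic
  sites between a sequence pair, mismatches penalised by
  (total polymorphisms) * gscale / (pair differences); gscale 0 means
  mismatches break fragments.  Significance is a permutation KA-style
  p-value, Bonferroni-corrected over pairs; only such "global inner"
  fragments are reported.

All permutation p-values carry the add-one correction
p = (1 + #extreme) / (n_perm + 1) and are reproducible under fixed seeds.

r/m post-processing consumes any per-site (S, R) posterior track: a site
is a mutation substitution when (1-R)*S >= 0.95, a recombination
substitution when R*S >= 0.95, and events are maximal runs with R >= 0.5
throughout containing at least one site with R >= 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PosteriorTrack", "Fragment", "RecombinationReport",
    "phi_test", "nss_test", "maxchi_test", "geneconv_fragments",
    "ensemble_vote", "classify_fragments", "rm_counts", "count_events",
]


# -- shared encoding --------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _encode(seqs: Mapping[str, str]) -> Tuple[List[str], np.ndarray]:
    labels = sorted(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    lens = {len(seqs[lab]) for lab in labels}
    if len(lens) != 1:
        raise ValueError("rows must have equal length")
    mat = np.full((len(labels), lens.pop()), 4, dtype=np.int8)
    for r, lab in enumerate(labels):
        for c, ch in enumerate(seqs[lab].upper()):
            mat[r, c] = _BASE_INDEX.get(ch, 4)
    return labels, mat


def _variable_columns(mat: np.ndarray) -> np.ndarray:
    """Columns with >= 2 distinct unambiguous states."""
    out = []
    for c in range(mat.shape[1]):
        col = mat[:, c]
        states = np.unique(col[col < 4])
        if len(states) >= 2:
            out.append(c)
    return np.array(out, dtype=int)


def _informative_columns(mat: np.ndarray) -> np.ndarray:
    """Parsimony-informative columns: >= 2 states each in >= 2 rows."""
    out = []
    for c in range(mat.shape[1]):
        col = mat[:, c]
        vals, counts = np.unique(col[col < 4], return_counts=True)
        if np.count_nonzero(counts >= 2) >= 2:
            out.append(c)
    return np.array(out, dtype=int)


def _extra_steps(a: Tuple[int, ...], b: Tuple[int, ...]) -> int:
    """Refined incompatibility of a character pair: the minimum number of
    extra state changes required on any tree carrying both sites, i.e. the
    cycle (cyclomatic) number of the bipartite partition intersection
    graph.  0 means the pair is compatible; for two binary characters this
    is the classic 0/1 four-gamete score."""
    edges = {(x, y) for x, y in zip(a, b) if x < 4 and y < 4}
    verts = ({("a", x) for x, _ in edges} | {("b", y) for _, y in edges})
    parent: Dict[object, object] = {v: v for v in verts}

    def find(v):
        while parent[v] is not v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    components = len(verts)
    for x, y in edges:
        ra, rb = find(("a", x)), find(("b", y))
        if ra != rb:
            parent[ra] = rb
            components -= 1
    return len(edges) - (len(verts) - components)


def _columns_compatible(a: Tuple[int, ...], b: Tuple[int, ...]) -> bool:
    """Compatibility: the pair admits a common homoplasy-free tree."""
    return _extra_steps(a, b) == 0


def _incompatibility_matrix(mat: np.ndarray, cols: np.ndarray,
                            refined: bool = False) -> np.ndarray:
    """Pairwise incompatibility between the given columns (0/1, or the
    refined extra-steps weight), computed once per distinct column-pattern
    pair."""
    patterns = [tuple(int(v) for v in mat[:, c]) for c in cols]
    uniq = sorted(set(patterns))
    pid = {p: i for i, p in enumerate(uniq)}
    ids = np.array([pid[p] for p in patterns])
    nu = len(uniq)
    inc_u = np.zeros((nu, nu))
    for i in range(nu):
        for j in range(i + 1, nu):
            w = _extra_steps(uniq[i], uniq[j])
            if not refined:
                w = 1.0 if w > 0 else 0.0
            inc_u[i, j] = inc_u[j, i] = w
    return inc_u[np.ix_(ids, ids)]


def _addone_p(n_extreme: int, n_perm: int) -> float:
    return (1 + n_extreme) / (n_perm + 1)


# -- Phi and NSS ------------------------------------------------------------

def phi_test(seqs: Mapping[str, str], window: int = 100,
             n_perm: int = 1000, seed: int = 0) -> float:
    """Pairwise homoplasy (Phi) permutation test.

    The statistic is the mean refined incompatibility (extra state
    changes) over ordered pairs of parsimony-informative sites at most
    ``window`` informative sites apart; recombination makes nearby sites
    more compatible, so the p-value is the fraction of site-order shuffles
    with a statistic as small or smaller.  Returns NaN when fewer than 2
    informative sites.
    """
    _, mat = _encode(seqs)
    cols = _informative_columns(mat)
    k = len(cols)
    if k < 2:
        return float("nan")
    inc = _incompatibility_matrix(mat, cols, refined=True)
    w = min(window, k - 1)

    def statistic(order: np.ndarray) -> float:
        total = 0.0
        n_pairs = 0
        for d in range(1, w + 1):
            total += inc[order[:-d], order[d:]].sum()
            n_pairs += k - d
        return total / n_pairs

    obs = statistic(np.arange(k))
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(k) for _ in range(n_perm)])
    null_total = np.zeros(n_perm)
    n_pairs = 0
    for d in range(1, w + 1):
        null_total += inc[perms[:, :-d], perms[:, d:]].sum(axis=1)
        n_pairs += k - d
    null = null_total / n_pairs
    return _addone_p(int(np.count_nonzero(null <= obs + 1e-12)), n_perm)


def nss_test(seqs: Mapping[str, str], n_perm: int = 1000,
             seed: int = 0) -> float:
    """Neighbour similarity score permutation test.

    NSS is the fraction of adjacent informative-site pairs that are
    compatible; recombination clusters compatible sites, so the p-value is
    the fraction of shuffles with NSS as large or larger.
    """
    _, mat = _encode(seqs)
    cols = _informative_columns(mat)
    k = len(cols)
    if k < 2:
        return float("nan")
    compat = 1.0 - _incompatibility_matrix(mat, cols)
    obs = compat[np.arange(k - 1), np.arange(1, k)].mean()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(k)
        null[i] = compat[p[:-1], p[1:]].mean()
    return _addone_p(int(np.count_nonzero(null >= obs - 1e-12)), n_perm)


# -- MaxChi -----------------------------------------------------------------

def _maxchi_stat(mismatch: np.ndarray,
                 window: Optional[int] = None) -> np.ndarray:
    """Per-breakpoint chi-square values for one (or many) mismatch vectors.

    ``mismatch`` has shape (..., L); breakpoint k = 1..L-1 splits the
    polymorphic columns into left [0:k) and right [k:L).  With a window,
    only ``window`` columns on each side enter the 2x2 table (breakpoints
    too close to the ends are skipped).  Returns chi2 of shape (..., L-1).
    """
    L = mismatch.shape[-1]
    cum = np.cumsum(mismatch, axis=-1)
    zero = np.zeros(mismatch.shape[:-1] + (1,))
    cum0 = np.concatenate([zero, cum], axis=-1)   # cum0[..., k] = sum[0:k)
    k = np.arange(1, L)
    if window is None or 2 * window >= L:
        a = cum0[..., 1:L]                        # mismatches left
        nl = k.astype(float)
        c = cum0[..., L:L + 1] - a                # mismatches right
        nr = (L - k).astype(float)
        valid = np.ones(L - 1, dtype=bool)
    else:
        w = int(window)
        lo = np.maximum(k - w, 0)
        hi = np.minimum(k + w, L)
        a = np.take(cum0, k, axis=-1) - np.take(cum0, lo, axis=-1)
        c = np.take(cum0, hi, axis=-1) - np.take(cum0, k, axis=-1)
        nl = (k - lo).astype(float)
        nr = (hi - k).astype(float)
        valid = (k >= w) & (k <= L - w)
    b = nl - a
    d = nr - c
    n = nl + nr
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return np.where(valid, chi2, 0.0)


def maxchi_test(seqs: Mapping[str, str], window: Optional[int] = None,
                n_perm: int = 1000, seed: int = 0
                ) -> Tuple[float, Dict[Tuple[str, str], Tuple[int, float]]]:
    """Maximum chi-square breakpoint permutation test.

    For every sequence pair a breakpoint slides over the polymorphic
    columns; the 2x2 table of (mismatch/match) x (left/right) gives a
    chi-square, and the statistic is the maximum over pairs and positions
    (``window`` limits each half to that many polymorphic columns; None
    uses the full halves).  The null permutes column order.  Returns the
    p-value and, per pair, the best breakpoint (1-based alignment
    coordinate of the first right-hand column) with its chi-square.
    """
    labels, mat = _encode(seqs)
    cols = _variable_columns(mat)
    L = len(cols)
    pairs = [(i, j) for i in range(len(labels))
             for j in range(i + 1, len(labels))]
    best: Dict[Tuple[str, str], Tuple[int, float]] = {}
    if L < 2:
        return 1.0, best
    sub = mat[:, cols]
    M = np.stack([(sub[i] != sub[j]) & (sub[i] < 4) & (sub[j] < 4)
                  for i, j in pairs]).astype(float)

    chi2 = _maxchi_stat(M, window)
    obs = float(chi2.max()) if chi2.size else 0.0
    for (pi, (i, j)) in enumerate(pairs):
        if chi2[pi].size == 0:
            continue
        kbest = int(np.argmax(chi2[pi]))
        best[(labels[i], labels[j])] = (int(cols[kbest + 1]) + 1,
                                        float(chi2[pi, kbest]))
    if obs <= 0:
        return 1.0, best
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(L)
        null[t] = _maxchi_stat(M[:, perm], window).max()
    p = _addone_p(int(np.count_nonzero(null >= obs - 1e-12)), n_perm)
    return p, best


# -- gene-conversion fragments ----------------------------------------------

@dataclass
class Fragment:
    """One candidate converted segment between a sequence pair."""

    pair: Tuple[str, str]
    start: int                 # 1-based inclusive alignment coordinates
    end: int
    score: float
    ka_p: float                # Bonferroni-corrected permutation p
    gscale: float = 1.0
    frag_class: Optional[str] = None   # within_A | within_B | between

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("bad fragment coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _best_segment(scores: np.ndarray, lo: int, hi: int
                  ) -> Tuple[int, int, float]:
    """Kadane maximum-scoring segment within [lo, hi)."""
    best = -np.inf
    best_span = (lo, lo)
    cur = 0.0
    cur_start = lo
    for k in range(lo, hi):
        if cur <= 0:
            cur = 0.0
            cur_start = k
        cur += scores[k]
        if cur > best:
            best = cur
            best_span = (cur_start, k)
    return best_span[0], best_span[1], float(best)


def _maximal_segments(scores: np.ndarray) -> List[Tuple[int, int, float]]:
    """Disjoint positive-scoring segments by recursive Kadane splitting."""
    out: List[Tuple[int, int, float]] = []
    spans = [(0, len(scores))]
    while spans:
        lo, hi = spans.pop()
        if hi - lo == 0:
            continue
        s, e, sc = _best_segment(scores, lo, hi)
        if sc <= 0:
            continue
        out.append((s, e, sc))
        spans.append((lo, s))
        spans.append((e + 1, hi))
    return sorted(out)


def _null_max_scores(L: int, n_mis: int, penalty: float, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Permutation null of the maximum segment score for one pair.

    Permuting the polymorphic-column order only shuffles the mismatch
    positions, so the null is drawn directly as random binary vectors
    (vectorized over permutations with a single pass over columns)."""
    pen = penalty if np.isfinite(penalty) else 1e12
    # build n_perm shuffled binary vectors without materialising L x n_perm
    # permutations: sample mismatch positions via argsort of uniforms
    u = rng.random((n_perm, L))
    thresh = np.partition(u, n_mis - 1, axis=1)[:, n_mis - 1:n_mis] \
        if n_mis > 0 else None
    cur = np.zeros(n_perm)
    best = np.zeros(n_perm)
    for c in range(L):
        if n_mis > 0:
            x = np.where(u[:, c] <= thresh[:, 0], -pen, 1.0)
        else:
            x = np.ones(n_perm)
        cur = np.maximum(cur + x, 0.0)
        best = np.maximum(best, cur)
    return best


def geneconv_fragments(seqs: Mapping[str, str], gscale: float = 1.0,
                       n_perm: int = 10000, seed: int = 0,
                       alpha: float = 0.05
                       ) -> Tuple[List[Fragment], float]:
    """Global inner gene-conversion fragments with permutation KA p-values.

    Polymorphic (variable) columns are walked per sequence pair scoring +1
    for a shared (matching) polymorphism and -penalty for a mismatch, with
    penalty = (total polymorphic columns) * gscale / (pair differences);
    gscale 0 makes any mismatch break a fragment.  Maximal-scoring
    segments are candidate fragments; each is tested against the
    permutation null of the pair's maximum segment score and
    Bonferroni-corrected over pairs.  Only fragments with corrected
    ka_p < ``alpha`` are returned, with 1-based inclusive coordinates on
    the original alignment.  The second return value is the gene-level
    (Bonferroni-corrected) p of the best fragment, 1.0 if none.
    """
    if gscale < 0:
        raise ValueError("gscale must be >= 0")
    labels, mat = _encode(seqs)
    if len(labels) < 3:
        raise ValueError("inner fragments need at least 3 sequences")
    cols = _variable_columns(mat)
    L = len(cols)
    if L == 0:
        return [], 1.0
    sub = mat[:, cols]
    pairs = [(i, j) for i in range(len(labels))
             for j in range(i + 1, len(labels))]
    n_pairs = len(pairs)
    rng = np.random.default_rng(seed)
    frags: List[Fragment] = []
    best_p = 1.0
    for i, j in pairs:
        mism = ((sub[i] != sub[j]) & (sub[i] < 4) & (sub[j] < 4))
        n_mis = int(mism.sum())
        if gscale == 0:
            penalty = np.inf
        else:
            penalty = (L * gscale / n_mis) if n_mis > 0 else np.inf
        scores = np.where(mism, -(penalty if np.isfinite(penalty) else 1e12),
                          1.0)
        segments = _maximal_segments(scores)
        if not segments:
            continue
        null = _null_max_scores(L, n_mis, penalty, n_perm, rng)
        for s, e, sc in segments:
            p_raw = _addone_p(int(np.count_nonzero(null >= sc - 1e-9)),
                              n_perm)
            ka_p = min(1.0, p_raw * n_pairs)
            best_p = min(best_p, ka_p)
            if ka_p < alpha:
                frags.append(Fragment(
                    pair=(labels[i], labels[j]),
                    start=int(cols[s]) + 1, end=int(cols[e]) + 1,
                    score=float(sc), ka_p=float(ka_p),
                    gscale=float(gscale)))
    frags.sort(key=lambda f: (f.ka_p, f.pair, f.start))
    return frags, best_p


# -- ensemble and classification --------------------------------------------

@dataclass
class RecombinationReport:
    gene_id: str
    p_values: Dict[str, float]           # NSS, MaxChi, Phi (NaN = NA)
    geneconv_pass: bool
    fragments: List[Fragment] = field(default_factory=list)
    tier: int = 0


def ensemble_vote(p_values: Mapping[str, float], geneconv_pass: bool,
                  alpha: float = 0.01) -> int:
    """Number of significant methods (0..4); NA (NaN) never counts.

    Phi/NSS/MaxChi are significant at p < alpha; the gene-conversion
    method is significant iff any global inner fragment passed its
    Bonferroni KA < 0.05 rule.
    """
    tier = 0
    for name in ("NSS", "MaxChi", "Phi"):
        p = p_values.get(name, float("nan"))
        if p is not None and not np.isnan(p) and p < alpha:
            tier += 1
    if geneconv_pass:
        tier += 1
    return tier


def classify_fragments(frags: Sequence[Fragment],
                       groups: Mapping[str, str]
                       ) -> Tuple[List[Fragment],
                                  Dict[Tuple[str, float], Dict[str, float]]]:
    """Attach within_A / within_B / between classes and summarise lengths.

    Summaries are keyed by (class, gscale) with min/median/max fragment
    length in bp.  An unlabelled genome is an error naming it.
    """
    out: List[Fragment] = []
    for f in frags:
        for g in f.pair:
            if g not in groups:
                raise KeyError(f"genome {g} has no group label")
        ga, gb = groups[f.pair[0]], groups[f.pair[1]]
        cls = f"within_{ga}" if ga == gb else "between"
        out.append(replace(f, frag_class=cls))
    summaries: Dict[Tuple[str, float], Dict[str, float]] = {}
    by_key: Dict[Tuple[str, float], List[int]] = {}
    for f in out:
        by_key.setdefault((f.frag_class, f.gscale), []).append(f.length)
    for key, lens in sorted(by_key.items()):
        arr = np.array(lens)
        summaries[key] = {"n": int(arr.size), "min": float(arr.min()),
                          "median": float(np.median(arr)),
                          "max": float(arr.max())}
    return out, summaries


# -- posterior tracks -------------------------------------------------------

@dataclass
class PosteriorTrack:
    """Per-site posterior probabilities of substitution (S) and
    recombination (R) along a concatenate."""

    S: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.S.shape != self.R.shape or self.S.ndim != 1:
            raise ValueError("S and R must be equal-length 1-D arrays")
        for name, arr in (("S", self.S), ("R", self.R)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} values must be probabilities")

    def __len__(self) -> int:
        return int(self.S.shape[0])


@dataclass
class RmCounts:
    n_mut: int
    n_rec: int
    r_over_m: float
    flags: Tuple[str, ...] = ()


def rm_counts(track: PosteriorTrack, threshold: float = 0.95) -> RmCounts:
    """Count substitution sites attributable to mutation vs recombination.

    A site counts as a mutation substitution when (1-R)*S >= threshold and
    as a recombination substitution when R*S >= threshold; r/m is their
    ratio (NaN, flagged, when no mutation sites qualify).
    """
    p_mut = (1.0 - track.R) * track.S
    p_rec = track.R * track.S
    n_mut = int(np.count_nonzero(p_mut >= threshold))
    n_rec = int(np.count_nonzero(p_rec >= threshold))
    if n_mut == 0:
        return RmCounts(n_mut, n_rec, float("nan"), ("undefined_r_over_m",))
    return RmCounts(n_mut, n_rec, n_rec / n_mut)


def count_events(track: PosteriorTrack, run_floor: float = 0.5,
                 peak: float = 0.95) -> int:
    """Recombination events: maximal runs with R >= run_floor throughout
    that contain at least one site with R >= peak."""
    above = track.R >= run_floor
    events = 0
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        has_peak = False
        while j < n and above[j]:
            if track.R[j] >= peak:
                has_peak = True
            j += 1
        if has_peak:
            events += 1
        i = j
    return events
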