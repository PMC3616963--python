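"""Unrooted leaf-labelled trees with branch lengths.

The tree is stored as a rooted view anchored at an internal node (the root
of an unrooted binary tree has three children; all other internal nodes are
binary).  Branch lengths live on the edge above each non-root node.  This
small structure is the substrate for likelihood computation, topology
enumeration, bipartition extraction and the weighted Robinson-Foulds
distance; newick import/export goes through dendropy.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "Tree",
    "parse_newick",
    "enumerate_topologies",
    "n_unrooted_topologies",
    "weighted_rf",
    "cluster_trees",
]


class Tree:
    """Mutable unrooted tree (rooted view at an internal trifurcation).

    Attributes
    ----------
    parent : list[int]
        Parent node index per node; -1 for the root.
    length : list[float]
        Length of the edge above each node (ignored for the root).
    label : list[str | None]
        Leaf label, or None for internal nodes.
    support : list[float | None]
        Optional bootstrap support (in %) for the edge above each node.
    """

    __slots__ = ("parent", "length", "label", "support", "root")

    def __init__(self) -> None:
        self.parent: List[int] = []
        self.length: List[float] = []
        self.label: List[Optional[str]] = []
        self.support: List[Optional[float]] = []
        self.root: int = -1

    # -- construction -----------------------------------------------------

    def _add_node(self, parent: int, length: float, label: Optional[str]) -> int:
        self.parent.append(parent)
        self.length.append(length)
        self.label.append(label)
        self.support.append(None)
        return len(self.parent) - 1

    @classmethod
    def star(cls, labels: Sequence[str], length: float = 0.05) -> "Tree":
        """Three-leaf star: the unique unrooted topology on 3 leaves."""
        if len(labels) != 3:
            raise ValueError("star() needs exactly 3 labels")
        t = cls()
        t.root = t._add_node(-1, 0.0, None)
        for lab in labels:
            t._add_node(t.root, length, lab)
        return t

    def copy(self) -> "Tree":
        t = Tree()
        t.parent = list(self.parent)
        t.length = list(self.length)
        t.label = list(self.label)
        t.support = list(self.support)
        t.root = self.root
        return t

    # -- topology queries --------------------------------------------------

    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self) -> Dict[int, List[int]]:
        ch: Dict[int, List[int]] = {i: [] for i in range(self.n_nodes())}
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def leaves(self) -> List[int]:
        return [i for i, lab in enumerate(self.label) if lab is not None]

    def leaf_labels(self) -> List[str]:
        return sorted(lab for lab in self.label if lab is not None)

    def postorder(self) -> List[int]:
        """All nodes, children before parents, root last."""
        ch = self.children()
        out: List[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(ch[node])
        out.reverse()
        return out

    def clade_leafsets(self) -> Dict[int, FrozenSet[str]]:
        """Leaf-label set below each node (in the rooted view)."""
        ch = self.children()
        sets: Dict[int, FrozenSet[str]] = {}
        for node in self.postorder():
            if self.label[node] is not None:
                sets[node] = frozenset([self.label[node]])
            else:
                acc: set = set()
                for c in ch[node]:
                    acc |= sets[c]
                sets[node] = frozenset(acc)
        return sets

    def _canon_split(self, side: FrozenSet[str], all_labels: FrozenSet[str]) -> FrozenSet[str]:
        ref = min(all_labels)
        return frozenset(all_labels - side) if ref in side else side

    def bipartitions(self, with_trivial: bool = False) -> Dict[FrozenSet[str], float]:
        """Map canonical split -> branch length for each edge.

        A split is represented by the side not containing the smallest leaf
        label.  Internal (non-trivial) edges only, unless ``with_trivial``.
        """
        all_labels = frozenset(self.leaf_labels())
        sets = self.clade_leafsets()
        out: Dict[FrozenSet[str], float] = {}
        for node in range(self.n_nodes()):
            if node == self.root:
                continue
            side = sets[node]
            if not with_trivial and (len(side) < 2 or len(side) > len(all_labels) - 2):
                continue
            key = self._canon_split(side, all_labels)
            out[key] = out.get(key, 0.0) + self.length[node]
        return out

    def split_supports(self) -> Dict[FrozenSet[str], Optional[float]]:
        all_labels = frozenset(self.leaf_labels())
        sets = self.clade_leafsets()
        out: Dict[FrozenSet[str], Optional[float]] = {}
        for node in range(self.n_nodes()):
            if node == self.root:
                continue
            side = sets[node]
            if len(side) < 2 or len(side) > len(all_labels) - 2:
                continue
            out[self._canon_split(side, all_labels)] = self.support[node]
        return out

    def has_split(self, side: Iterable[str]) -> bool:
        all_labels = frozenset(self.leaf_labels())
        key = self._canon_split(frozenset(side), all_labels)
        return key in self.bipartitions()

    def topology_key(self) -> str:
        """Canonical topology string (lengths dropped, children sorted)."""
        ch = self.children()

        def rec(node: int) -> str:
            if self.label[node] is not None:
                return self.label[node]
            parts = sorted(rec(c) for c in ch[node])
            return "(" + ",".join(parts) + ")"

        # canonical rooting: reroot conceptually at the smallest leaf's edge
        # is not needed for comparing trees built over the same leaf set as
        # long as the string is invariant; we use the sorted multiset of
        # canonical splits which is fully rooting-invariant.
        splits = sorted(",".join(sorted(s)) for s in self.bipartitions())
        return ";".join(splits) if splits else rec(self.root)

    # -- editing -----------------------------------------------------------

    def insert_leaf_on_edge(self, edge_child: int, new_label: str,
                            pendant: float = 0.05, split_at: float = 0.5) -> int:
        """Insert a new leaf by breaking the edge above ``edge_child``."""
        old_parent = self.parent[edge_child]
        if old_parent < 0:
            raise ValueError("cannot insert on the root's (nonexistent) parent edge")
        old_len = self.length[edge_child]
        mid = self._add_node(old_parent, old_len * (1 - split_at), None)
        self.parent[edge_child] = mid
        self.length[edge_child] = old_len * split_at
        return self._add_node(mid, pendant, new_label)

    def find_leaf(self, label: str) -> int:
        for i, lab in enumerate(self.label):
            if lab == label:
                return i
        raise KeyError(label)

    def remove_leaf(self, label: str) -> "Tree":
        """Return a compacted copy with the leaf removed and the resulting
        degree-2 node suppressed."""
        t = self.copy()
        leaf = t.find_leaf(label)
        par = t.parent[leaf]
        ch = t.children()
        # drop the leaf
        keep = [i for i in range(t.n_nodes()) if i != leaf]
        siblings = [c for c in ch[par] if c != leaf]
        if par == t.root:
            if len(siblings) == 2:
                # root becomes degree-2: reroot at one sibling internal node,
                # or merge the two sibling edges if one is internal
                a, b = siblings
                internal = a if t.label[a] is None else (b if t.label[b] is None else None)
                if internal is None:
                    raise ValueError("cannot remove leaf from a 3-leaf tree")
                other = b if internal == a else a
                # make `internal` the new root; `other` hangs from it
                t.parent[other] = internal
                t.length[other] = t.length[other] + t.length[internal]
                t.parent[internal] = -1
                t.length[internal] = 0.0
                t.root = internal
                keep = [i for i in keep if i != par]
        else:
            # par becomes degree-2 (one child + its parent): splice it out
            (sib,) = siblings
            t.parent[sib] = t.parent[par]
            t.length[sib] = t.length[sib] + t.length[par]
            keep = [i for i in keep if i != par]
        return t._compact(keep)

    def _compact(self, keep: List[int]) -> "Tree":
        remap = {old: new for new, old in enumerate(keep)}
        t = Tree()
        for old in keep:
            p = self.parent[old]
            t.parent.append(remap[p] if p in remap else -1)
            t.length.append(self.length[old])
            t.label.append(self.label[old])
            t.support.append(self.support[old])
        t.root = remap[self.root]
        return t

    def attach_leaf_near_leaf(self, target_label: str, new_label: str,
                              attach_dist: float, pendant: float) -> "Tree":
        """Copy with ``new_label`` grafted onto the pendant edge of
        ``target_label`` at ``attach_dist`` above the target tip."""
        t = self.copy()
        target = t.find_leaf(target_label)
        d = min(attach_dist, t.length[target] * 0.999) if t.length[target] > 0 else 0.0
        old_len = t.length[target]
        mid = t._add_node(t.parent[target], max(old_len - d, 0.0), None)
        t.parent[target] = mid
        t.length[target] = d
        t._add_node(mid, pendant, new_label)
        return t

    # -- newick ------------------------------------------------------------

    def newick(self, lengths: bool = True, support: bool = False) -> str:
        ch = self.children()

        def rec(node: int) -> str:
            if self.label[node] is not None:
                s = self.label[node]
            else:
                s = "(" + ",".join(rec(c) for c in ch[node]) + ")"
                if support and self.support[node] is not None:
                    s += format(self.support[node], "g")
            if lengths and node != self.root:
                s += f":{self.length[node]:.10g}"
            return s

        return rec(self.root) + ";"


def leaf_distances(tree: Tree):
    """Path-length distance matrix between leaves.

    Returns (labels, D) with labels sorted and D symmetric with zero
    diagonal.
    """
    labels = tree.leaf_labels()
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def path_to_root(node: int):
        out = {}
        depth = 0.0
        while node != -1:
            out[node] = depth
            depth += tree.length[node] if tree.parent[node] != -1 else 0.0
            node = tree.parent[node]
        return out

    leaf_nodes = [(tree.find_leaf(lab), lab) for lab in labels]
    paths = {node: path_to_root(node) for node, _ in leaf_nodes}
    for (na, la), (nb, lb) in itertools.combinations(leaf_nodes, 2):
        pa, pb = paths[na], paths[nb]
        best = min(pa[k] + pb[k] for k in pa.keys() & pb.keys())
        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = best
    return labels, d


def parse_newick(text: str) -> Tree:
    """Parse a newick string (internal-node labels read as supports)."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=True)
    # deroot a bifurcating root so the structure is genuinely unrooted
    # (keep a plain 2-leaf tree as a single edge with a degree-2 junction)
    if (len(dt.seed_node.child_nodes()) == 2
            and len(dt.leaf_nodes()) > 2):
        dt.collapse_basal_bifurcation()

    t = Tree()

    def rec(dnode, parent_idx: int) -> None:
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        idx = t._add_node(parent_idx, float(length), label)
        if label is None and dnode.label not in (None, ""):
            try:
                t.support[idx] = float(dnode.label)
            except ValueError:
                pass
        if parent_idx == -1:
            t.root = idx
        for c in dnode.child_nodes():
            rec(c, idx)

    rec(dt.seed_node, -1)
    return t


def n_unrooted_topologies(n_taxa: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies."""
    out = 1
    for k in range(3, 2 * n_taxa - 4, 2):
        out *= k
    return out


def enumerate_topologies(labels: Sequence[str], length: float = 0.05) -> List[Tree]:
    """All unrooted binary topologies over ``labels`` by stepwise insertion.

    Deterministic: labels are processed in sorted order and edges in node
    order, so the output ordering is reproducible.
    """
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    trees = [Tree.star(labels[:3], length=length)]
    for lab in labels[3:]:
        nxt: List[Tree] = []
        for t in trees:
            for node in range(t.n_nodes()):
                if node == t.root:
                    continue
                t2 = t.copy()
                t2.insert_leaf_on_edge(node, lab, pendant=length)
                nxt.append(t2)
        trees = nxt
    return trees


def weighted_rf(t1: Tree, t2: Tree) -> float:
    """Branch-score weighted Robinson-Foulds distance.

    Sum of |w1 - w2| over the union of internal bipartitions, an absent
    bipartition contributing weight 0.
    """
    if set(t1.leaf_labels()) != set(t2.leaf_labels()):
        raise ValueError("trees have different leaf sets")
    b1 = t1.bipartitions()
    b2 = t2.bipartitions()
    keys = set(b1) | set(b2)
    return float(sum(abs(b1.get(k, 0.0) - b2.get(k, 0.0)) for k in keys))


def cluster_trees(trees: Sequence[Tree], linkage: str = "complete",
                  cutoff: float = 1.0) -> np.ndarray:
    """Agglomerative clustering of trees on the weighted-RF matrix.

    Complete linkage cut at ``cutoff`` height.  Labels are renumbered by
    first appearance so the output is invariant to scipy's internal
    ordering.
    """
    from scipy.cluster.hierarchy import fcluster
    from scipy.cluster.hierarchy import linkage as scipy_linkage
    from scipy.spatial.distance import squareform

    n = len(trees)
    if n < 2:
        raise ValueError("need at least 2 trees")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = weighted_rf(trees[i], trees[j])
    z = scipy_linkage(squareform(dm, checks=False), method=linkage)
    raw = fcluster(z, t=cutoff, criterion="distance")
    remap: Dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        out[i] = remap[r]
    return out
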