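"""Synthetic sequence evolution for a two-clade species tree.

Generates the inputs the downstream analysis consumes, with ground truth:

* gap-free nucleotide (optionally codon-aware) alignments evolved under
  GTR(+Gamma) along a fixed 6-taxon, two-clade species tree;
* homologous-replacement recombination tracts, applied by regrafting the
  recipient lineage next to the donor and re-evolving the tract;
* per-gene trees with randomized within-clade histories — the whole-gene
  limit of free within-clade recombination;
* plateau-shaped per-site posterior substitution/recombination tracks;
* proteome sets with planted clade-specific genes and pseudogenes.

All randomness flows from ``SimParams.seed`` (or an explicit generator)
through per-operation ``numpy`` generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .gtr import DNA, GTRParams, eigendecompose, transition_matrices
from .trees import Tree, leaf_distances, parse_newick

_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA

DEFAULT_GROUPS = {
    "wMel": "A", "wRi": "A", "wHa": "A",
    "wPip": "B", "wAlbB": "B", "wNo": "B",
}

_DEFAULT_NEWICK = (
    "((wRi:0.010,wHa:0.010):0.018,wMel:0.014,"
    "((wPip:0.024,wAlbB:0.024):0.022,wNo:0.034):0.35);"
)


@dataclass
class SpeciesTree:
    """Leaf-labelled species tree plus a leaf -> clade (group) map."""

    tree: Tree
    clade_map: Dict[str, str]

    def __post_init__(self) -> None:
        leaves = set(self.tree.leaf_labels())
        if leaves != set(self.clade_map):
            raise ValueError("clade_map must label exactly the tree's leaves")
        if any(l < 0 for l in self.tree.length):
            raise ValueError("branch lengths must be non-negative")

    def groups(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for leaf, g in sorted(self.clade_map.items()):
            out.setdefault(g, []).append(leaf)
        return out


def default_species_tree() -> SpeciesTree:
    """The fixed two-clade (3+3) reference scenario.

    Branch lengths are set so pairwise divergences fall on the scales seen
    between closely related strains within clades (~0.02-0.08
    substitutions/site) versus across the deep split (~0.4 expected,
    ~0.3 observed after multiple hits).  The within-clade internal
    branches are long enough that a clonal 1-kb gene resolves its
    within-clade relationships reliably.
    """
    return SpeciesTree(parse_newick(_DEFAULT_NEWICK), dict(DEFAULT_GROUPS))


@dataclass
class SimParams:
    """Parameters of one simulated gene.

    Tract-transfer event counts are Poisson with the given expectations;
    tract lengths are geometric with the given means (bp).
    """

    gtr_rates: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]))
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.array([0.33, 0.17, 0.17, 0.33]))
    gamma_shape: Optional[float] = 1.0
    seq_length: int = 1002
    rec_rate_within: float = 0.0
    rec_rate_between: float = 0.0
    tract_mean_within: float = 500.0
    tract_mean_between: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.gtr_rates = np.asarray(self.gtr_rates, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if abs(self.base_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if np.any(self.gtr_rates <= 0):
            raise ValueError("GTR exchangeabilities must be positive")
        if self.tract_mean_within < 1 or self.tract_mean_between < 1:
            raise ValueError("tract means must be >= 1 bp")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")

    def gtr(self) -> GTRParams:
        return GTRParams(self.gtr_rates.copy(), self.base_freqs.copy(),
                         self.gamma_shape)


@dataclass
class TractEvent:
    donor: str
    recipient: str
    start: int   # 1-based inclusive
    end: int
    kind: str    # "within" | "between"


@dataclass
class SimulatedGene:
    labels: List[str]
    states: np.ndarray            # (n_taxa, n_sites) int8 in 0..3
    truth_log: List[TractEvent]
    generating_topology: str

    @property
    def n_sites(self) -> int:
        return int(self.states.shape[1])

    def sequences(self) -> Dict[str, str]:
        lut = np.frombuffer(DNA.encode(), dtype=np.uint8)
        return {lab: lut[row].tobytes().decode()
                for lab, row in zip(self.labels, self.states)}


def _evolve(tree: Tree, params: GTRParams, n_sites: int,
            rng: np.random.Generator) -> Tuple[List[str], np.ndarray]:
    """Evolve independent sites under GTR(+Gamma) along ``tree``."""
    lam, u, v = eigendecompose(params)
    rates = params.rate_categories()
    site_cat = rng.integers(0, len(rates), size=n_sites)
    node_states = np.empty((tree.n_nodes(), n_sites), dtype=np.int8)
    node_states[tree.root] = rng.choice(4, size=n_sites, p=params.base_freqs)
    order = tree.postorder()[::-1]          # preorder: parents first
    for node in order:
        if node == tree.root:
            continue
        p = transition_matrices(lam, u, v,
                                np.array([tree.length[node]]), rates)[0]
        parent_states = node_states[tree.parent[node]]
        child = np.empty(n_sites, dtype=np.int8)
        for c in range(len(rates)):
            mask = site_cat == c
            if not mask.any():
                continue
            cum = np.cumsum(p[c], axis=1)
            uu = rng.random(mask.sum())
            child[mask] = (uu[:, None] > cum[parent_states[mask]]).sum(axis=1)
        node_states[node] = child
    labels = tree.leaf_labels()
    rows = np.stack([node_states[tree.find_leaf(lab)] for lab in labels])
    return labels, rows


def _stop_codon_columns(rows: np.ndarray) -> np.ndarray:
    """Indices of codon columns where any row carries a stop codon."""
    n = rows.shape[1] // 3
    cod = rows[:, : 3 * n].reshape(rows.shape[0], n, 3)
    bad = np.zeros(n, dtype=bool)
    for s in _STOP_CODONS:
        bad |= ((cod[:, :, 0] == s[0]) & (cod[:, :, 1] == s[1])
                & (cod[:, :, 2] == s[2])).any(axis=0)
    return np.nonzero(bad)[0]


def simulate_gene(species: SpeciesTree, params: SimParams,
                  codon_aware: bool = False) -> SimulatedGene:
    """Simulate one gap-free gene alignment clonally along the species tree.

    With ``codon_aware`` the length must be a multiple of 3 and codon
    columns that would place a stop codon in any taxon are re-drawn, so
    every row is a valid (stop-free) coding frame.
    """
    if codon_aware and params.seq_length % 3 != 0:
        raise ValueError("codon-aware simulation needs seq_length % 3 == 0")
    rng = np.random.default_rng([params.seed, 0])
    gp = params.gtr()
    labels, rows = _evolve(species.tree, gp, params.seq_length, rng)
    if codon_aware:
        for _ in range(200):
            bad = _stop_codon_columns(rows)
            if bad.size == 0:
                break
            _, fresh = _evolve(species.tree, gp, 3 * bad.size, rng)
            for k, col in enumerate(bad):
                rows[:, 3 * col: 3 * col + 3] = fresh[:, 3 * k: 3 * k + 3]
        else:
            raise RuntimeError("could not draw stop-free codon columns")
    return SimulatedGene(labels, rows, [], species.tree.topology_key())


def _regraft_unsampled(species: SpeciesTree, recipient: str,
                       phantom_depth: float) -> Tree:
    """Regraft the recipient as a basal lineage of its own clade.

    Models a gene-conversion donor drawn from the clade's wider gene pool
    (an unsampled strain): inside the tract the recipient coalesces with
    its clade near the clade root, at pendant depth ``phantom_depth``.
    """
    group = species.clade_map[recipient]
    own_rest = {l for l, g in species.clade_map.items()
                if g == group and l != recipient}
    other = {l for l, g in species.clade_map.items() if g != group}
    t = species.tree.remove_leaf(recipient)
    sets = t.clade_leafsets()
    for node in range(t.n_nodes()):
        if node == t.root:
            continue
        if sets[node] == own_rest:
            # child side is the recipient's clade: attach near the child
            t2 = t.copy()
            t2.insert_leaf_on_edge(node, recipient, pendant=phantom_depth,
                                   split_at=0.1)
            return t2
        if sets[node] == other:
            # child side is the other clade: attach near the parent
            t2 = t.copy()
            t2.insert_leaf_on_edge(node, recipient, pendant=phantom_depth,
                                   split_at=0.9)
            return t2
    raise RuntimeError("could not locate the central edge")


def _apply_tract(rows: np.ndarray, labels: List[str], species: SpeciesTree,
                 gp: GTRParams, donor: str, recipient: str,
                 start: int, end: int, rng: np.random.Generator,
                 attach_dist: float,
                 phantom_depth: float = 0.04) -> None:
    """Re-evolve columns [start, end] (1-based inclusive) with the
    recipient regrafted onto the donor's pendant edge; edits rows in
    place.  ``donor='unsampled'`` instead regrafts the recipient as a
    basal lineage of its own clade (a donor from the clade's unsampled
    gene pool)."""
    if donor == "unsampled":
        regrafted = _regraft_unsampled(species, recipient, phantom_depth)
    else:
        regrafted = species.tree.remove_leaf(recipient).attach_leaf_near_leaf(
            donor, recipient, attach_dist=attach_dist, pendant=attach_dist)
    labels2, fresh = _evolve(regrafted, gp, end - start + 1, rng)
    row_of = {lab: i for i, lab in enumerate(labels)}
    for lab in labels:
        rows[row_of[lab], start - 1: end] = fresh[labels2.index(lab)]


def plant_tract(gene: SimulatedGene, species: SpeciesTree, params: SimParams,
                donor: str, recipient: str, start: int, end: int,
                attach_dist: float = 1e-4) -> SimulatedGene:
    """Apply one fully specified homologous-replacement tract.

    Deterministic counterpart of ``apply_recombination`` for controlled
    power experiments: the donor, recipient and tract coordinates
    (1-based inclusive) are given rather than drawn.
    """
    if not 1 <= start <= end <= gene.n_sites:
        raise ValueError("tract coordinates out of bounds")
    rng = np.random.default_rng([params.seed, 5])
    rows = gene.states.copy()
    _apply_tract(rows, gene.labels, species, params.gtr(), donor, recipient,
                 start, end, rng, attach_dist)
    if donor == "unsampled":
        kind = "within"
    else:
        kind = ("within"
                if species.clade_map[donor] == species.clade_map[recipient]
                else "between")
    log = list(gene.truth_log) + [TractEvent(donor, recipient, start, end,
                                             kind)]
    return SimulatedGene(list(gene.labels), rows, log,
                         gene.generating_topology)


def apply_recombination(gene: SimulatedGene, species: SpeciesTree,
                        params: SimParams,
                        attach_dist: float = 1e-4) -> SimulatedGene:
    """Overlay homologous-replacement tracts on a simulated gene.

    Event counts are Poisson(rec_rate_within) and Poisson(rec_rate_between).
    For each event the recipient lineage is regrafted onto the donor's
    pendant edge (coalescing near the present, i.e. a recent transfer) and
    the tract columns are re-evolved for all taxa on that regrafted tree.
    The returned gene is a new object; the truth log records events in the
    order applied.
    """
    rng = np.random.default_rng([params.seed, 1])
    n_within = rng.poisson(params.rec_rate_within)
    n_between = rng.poisson(params.rec_rate_between)
    if n_within + n_between == 0:
        return SimulatedGene(list(gene.labels), gene.states.copy(),
                             list(gene.truth_log), gene.generating_topology)
    kinds = ["within"] * n_within + ["between"] * n_between
    rng.shuffle(kinds)
    rows = gene.states.copy()
    log = list(gene.truth_log)
    gp = params.gtr()
    length = gene.n_sites
    for kind in kinds:
        recipient = str(rng.choice(gene.labels))
        group = species.clade_map[recipient]
        if kind == "within":
            pool = [l for l in gene.labels
                    if species.clade_map[l] == group and l != recipient]
        else:
            pool = [l for l in gene.labels if species.clade_map[l] != group]
        donor = str(rng.choice(pool))
        mean = (params.tract_mean_within if kind == "within"
                else params.tract_mean_between)
        start = int(rng.integers(1, length + 1))
        tract_len = int(rng.geometric(1.0 / mean))
        end = min(start + tract_len - 1, length)
        _apply_tract(rows, gene.labels, species, gp, donor, recipient,
                     start, end, rng, attach_dist)
        log.append(TractEvent(donor, recipient, start, end, kind))
    return SimulatedGene(list(gene.labels), rows, log,
                         gene.generating_topology)


def sample_gene_tree(species: SpeciesTree, rng: np.random.Generator,
                     randomize_topology: bool = True,
                     recent_fraction: float = 0.75,
                     recent_scale: float = 0.08,
                     rate_sigma: float = 0.5) -> Tree:
    """Draw a per-gene tree with randomized within-clade histories.

    This is the whole-gene limit of free within-clade recombination: each
    clade's per-gene genealogy is an independent small coalescent.  The
    cherry pair is drawn uniformly (the three resolutions equally likely);
    its coalescence time T1 is a two-component exponential mixture — with
    probability ``recent_fraction`` the pair coalesces on the recent
    (within-population) scale ``recent_scale`` x the clade's base time, as
    a fresh conversion tract would make it, otherwise on the deep scale —
    and the third lineage joins after an additional exponential time.
    Per-lineage lognormal rate multipliers (``rate_sigma``) break the
    molecular clock.  The deep split between the clades is always
    retained, its length varying only mildly.  Base times are measured
    from the species tree so the clonal and randomized scenarios share
    the same average divergence scales.
    """
    groups = species.groups()
    if len(groups) != 2 or any(len(v) != 3 for v in groups.values()):
        raise ValueError("gene-tree sampling needs two clades of 3 leaves")
    labels, d = leaf_distances(species.tree)
    idx = {lab: i for i, lab in enumerate(labels)}

    gnames = sorted(groups)
    plan = {}
    depth = {}
    for g in gnames:
        members = groups[g]
        pairs = [(a, b) for i, a in enumerate(members)
                 for b in members[i + 1:]]
        within = {p: d[idx[p[0]], idx[p[1]]] for p in pairs}
        sp_cherry = min(within, key=within.get)
        sp_third = next(m for m in members if m not in sp_cherry)
        t_base = within[sp_cherry] / 2.0
        inc_base = max((np.mean([d[idx[sp_third], idx[sp_cherry[0]]],
                                 d[idx[sp_third], idx[sp_cherry[1]]]])
                        - t_base) / 2.0, 1e-3)
        cherry = (pairs[int(rng.integers(0, 3))] if randomize_topology
                  else sp_cherry)
        third = next(m for m in members if m not in cherry)
        plan[g] = (cherry, third, t_base, inc_base)
        depth[g] = (2 * (t_base + inc_base) + inc_base) / 3.0
    between = np.mean([d[idx[a], idx[b]]
                       for a in groups[gnames[0]] for b in groups[gnames[1]]])
    central = max(between - depth[gnames[0]] - depth[gnames[1]], 0.01)

    # scale of the deep mixture component keeps E[T1] at the clade base
    deep_scale = ((1.0 - recent_fraction * recent_scale)
                  / max(1.0 - recent_fraction, 1e-9))

    t = Tree()
    root = t._add_node(-1, 0.0, None)
    t.root = root
    # the deep split varies only mildly: recombination is free within
    # clades, so gene histories always retain the clade separation
    central_mult = float(np.exp(rng.normal(0.0, 0.3)))
    hubs = {gnames[0]: root,
            gnames[1]: t._add_node(root, central * central_mult, None)}
    for g in gnames:
        cherry, third, t_base, inc_base = plan[g]
        scale = (recent_scale if rng.random() < recent_fraction
                 else deep_scale)
        t1 = t_base * scale * rng.exponential()
        t2 = t1 + inc_base * rng.exponential()
        rates = np.exp(rng.normal(0.0, rate_sigma, size=3))
        cnode = t._add_node(hubs[g], max(t2 - t1, 1e-4), None)
        t._add_node(cnode, t1 * rates[0], cherry[0])
        t._add_node(cnode, t1 * rates[1], cherry[1])
        t._add_node(hubs[g], t2 * rates[2], third)
    return t


def simulate_gene_on_tree(gene_tree: Tree, species: SpeciesTree,
                          params: SimParams,
                          codon_aware: bool = False) -> SimulatedGene:
    """Clonal simulation along an arbitrary gene tree over the same leaves."""
    per_gene = SpeciesTree(gene_tree, dict(species.clade_map))
    out = simulate_gene(per_gene, params, codon_aware=codon_aware)
    return SimulatedGene(out.labels, out.states, out.truth_log,
                         gene_tree.topology_key())


# -- posterior tracks -------------------------------------------------------

def simulate_posterior_track(n_sites: int,
                             events: Sequence[Tuple[int, int, float]],
                             background_R: float,
                             S_values=1.0,
                             jitter: float = 0.0,
                             seed: int = 0):
    """Plateau-shaped per-site (S, R) posterior track.

    ``events`` are (start, end, plateau_R) with 1-based inclusive
    coordinates and must not overlap.  Inside an event R equals the plateau
    minus an optional downward jitter (< 0.05); outside it equals
    ``background_R``.  S may be a scalar or a per-site array.
    """
    from .recomb import PosteriorTrack

    if not 0.0 <= background_R <= 1.0:
        raise ValueError("background_R must be a probability")
    if not 0.0 <= jitter < 0.05:
        raise ValueError("jitter must be in [0, 0.05)")
    s = np.broadcast_to(np.asarray(S_values, dtype=float), (n_sites,)).copy()
    if np.any((s < 0) | (s > 1)):
        raise ValueError("S values must be probabilities")
    ordered = sorted(events)
    prev_end = 0
    for start, end, plateau in ordered:
        if start < 1 or end > n_sites or start > end:
            raise ValueError(f"event ({start}, {end}) out of bounds")
        if start <= prev_end:
            raise ValueError("events overlap")
        if not 0.0 <= plateau <= 1.0:
            raise ValueError("plateau must be a probability")
        prev_end = end
    rng = np.random.default_rng([seed, 2])
    r = np.full(n_sites, float(background_R))
    for start, end, plateau in ordered:
        width = end - start + 1
        vals = np.full(width, plateau)
        if jitter > 0:
            vals = vals - rng.uniform(0.0, jitter, size=width)
        r[start - 1: end] = np.clip(vals, 0.0, 1.0)
    return PosteriorTrack(S=s, R=r)


# -- proteomes --------------------------------------------------------------

_SENSE_CODONS = [a + b + c for a in DNA for b in DNA for c in DNA
                 if a + b + c not in ("TAA", "TAG", "TGA")]


@dataclass
class ProteomeSet:
    """Labelled protein+CDS sets with a planted truth table.

    ``proteins``/``cds`` map genome -> {gene_id: sequence}.  ``truth`` rows
    are (family_id, family_class, pseudogene_in) where family_class is
    ``core``, ``A_specific`` or ``B_specific`` and pseudogene_in lists the
    other-clade genomes carrying a disrupted remnant.  ``pseudogene_cds``
    holds those remnant nucleotide sequences.
    """

    groups: Dict[str, str]
    proteins: Dict[str, Dict[str, str]]
    cds: Dict[str, Dict[str, str]]
    truth: List[Tuple[str, str, Tuple[str, ...]]]
    pseudogene_cds: Dict[Tuple[str, str], str]

    def gene_ids(self, genome: str) -> List[str]:
        return sorted(self.proteins[genome])


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate(table=11))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(_SENSE_CODONS[i] for i in
                   rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1))
    return "ATG" + body


def _mutate_cds(cds: str, rng: np.random.Generator, rate: float) -> str:
    arr = np.frombuffer(cds.encode(), dtype=np.uint8).copy()
    lut = {ord(b): i for i, b in enumerate(DNA)}
    n_mut = rng.binomial(len(arr) - 3, rate)
    positions = rng.choice(np.arange(3, len(arr)), size=n_mut, replace=False)
    for pos in positions:
        cur = lut[arr[pos]]
        new = (cur + 1 + int(rng.integers(0, 3))) % 4
        old = arr[pos]
        arr[pos] = ord(DNA[new])
        codon = arr[pos - pos % 3: pos - pos % 3 + 3].tobytes().decode()
        if codon in ("TAA", "TAG", "TGA"):
            arr[pos] = old
    return arr.tobytes().decode()


def _disrupt_cds(cds: str, rng: np.random.Generator) -> str:
    """Introduce an internal stop or a frameshift into a CDS copy."""
    arr = list(cds)
    mid = len(arr) // 6 * 3 + 3
    if rng.random() < 0.5:
        arr[mid: mid + 3] = list("TAA")
        return "".join(arr)
    del arr[mid]
    return "".join(arr)


def simulate_proteomes(n_per_group: int = 3, n_core: int = 40,
                       n_specific_per_group=(33, 24),
                       pseudogene_fraction: float = 0.25,
                       seed: int = 0,
                       groups: Optional[Dict[str, str]] = None,
                       within_divergence: float = 0.02,
                       between_divergence: float = 0.15) -> ProteomeSet:
    """Plant core and clade-specific gene families across labelled genomes.

    Core families are single-copy in every genome; clade-specific families
    occur only in their clade's genomes, except that a
    ``pseudogene_fraction`` of them leave a disrupted (internal stop or
    frameshift) remnant in every genome of the other clade.  The default
    specific counts (33, 24) mirror the shape of the study system this
    package targets.
    """
    if isinstance(n_specific_per_group, int):
        n_specific_per_group = (n_specific_per_group, n_specific_per_group)
    rng = np.random.default_rng([seed, 3])
    if groups is None:
        a = [f"A{i+1}" for i in range(n_per_group)]
        b = [f"B{i+1}" for i in range(n_per_group)]
        groups = {**{g: "A" for g in a}, **{g: "B" for g in b}}
    genomes = sorted(groups)
    by_group: Dict[str, List[str]] = {}
    for g, lab in sorted(groups.items()):
        by_group.setdefault(lab, []).append(g)

    proteins: Dict[str, Dict[str, str]] = {g: {} for g in genomes}
    cds: Dict[str, Dict[str, str]] = {g: {} for g in genomes}
    truth: List[Tuple[str, str, Tuple[str, ...]]] = []
    pseudo: Dict[Tuple[str, str], str] = {}

    def plant(family_id: str, member_genomes: List[str]) -> str:
        n_codons = int(rng.integers(90, 300))
        ancestral = _random_cds(rng, n_codons)
        member_labels = {groups[g] for g in member_genomes}
        # per-clade ancestors so cross-clade members are more divergent
        clade_anc = {lab: (_mutate_cds(ancestral, rng, between_divergence / 2)
                           if len(member_labels) > 1 else ancestral)
                     for lab in member_labels}
        for g in member_genomes:
            variant = _mutate_cds(clade_anc[groups[g]], rng, within_divergence)
            gid = f"{g}_{family_id}"
            cds[g][gid] = variant
            proteins[g][gid] = _translate(variant)
        return ancestral

    for k in range(n_core):
        fam = f"core{k:04d}"
        plant(fam, genomes)
        truth.append((fam, "core", ()))
    for label, n_specific in zip(("A", "B"), n_specific_per_group):
        other = "B" if label == "A" else "A"
        for k in range(n_specific):
            fam = f"{label.lower()}spec{k:04d}"
            anc = plant(fam, by_group[label])
            remnant_in: Tuple[str, ...] = ()
            if rng.random() < pseudogene_fraction:
                remnant_in = tuple(by_group[other])
                for g in remnant_in:
                    remnant = _disrupt_cds(
                        _mutate_cds(anc, rng, between_divergence), rng)
                    pseudo[(fam, g)] = remnant
            truth.append((fam, f"{label}_specific", remnant_in))
    return ProteomeSet(dict(groups), proteins, cds, truth, pseudo)


def truth_search_hits(proteomes: ProteomeSet, seed: int = 0):
    """Homology-search evidence implied by the planted truth table.

    Emulates the outcome of searching each clade-specific family against
    the genomes outside its clade: pseudogenized remnants yield strong but
    disrupted hits, genuinely absent families yield either nothing or an
    occasional sub-threshold spurious hit.  Returns
    {family_id: {outside_genome: [SearchHit, ...]}}.
    """
    from .genecontent import SearchHit

    rng = np.random.default_rng([seed, 4])
    members: Dict[str, set] = {}
    for fam, cls, _ in proteomes.truth:
        if cls == "core":
            members[fam] = set(proteomes.groups)
        else:
            lab = cls[0]
            members[fam] = {g for g, l in proteomes.groups.items() if l == lab}
    out: Dict[str, Dict[str, list]] = {}
    for fam, cls, remnant_in in proteomes.truth:
        per_genome: Dict[str, list] = {}
        for genome in sorted(set(proteomes.groups) - members[fam]):
            hits = []
            if genome in remnant_in:
                hits.append(SearchHit(
                    query_gene=fam, target_genome=genome,
                    evalue=10.0 ** -float(rng.uniform(21, 60)),
                    fraction_aligned=float(rng.uniform(0.6, 0.95)),
                    pct_identity=float(rng.uniform(45, 75)),
                    disrupted=True))
            elif rng.random() < 0.1:
                hits.append(SearchHit(
                    query_gene=fam, target_genome=genome,
                    evalue=10.0 ** -float(rng.uniform(0.3, 3.5)),
                    fraction_aligned=float(rng.uniform(0.05, 0.25)),
                    pct_identity=float(rng.uniform(25, 40)),
                    disrupted=False))
            per_genome[genome] = hits
        out[fam] = per_genome
    return out


def truth_similarity_edges(proteomes: ProteomeSet):
    """All-vs-all protein similarity edges implied by the planted families.

    Returns (edges, lengths): one SimilarityEdge per within-family pair of
    members, with percent identity measured on the actual planted protein
    sequences, plus the protein length map the homology filter needs.
    """
    from .orthology import SimilarityEdge

    lengths = {f"{g}|{gid}": len(seq)
               for g in proteomes.proteins
               for gid, seq in proteomes.proteins[g].items()}
    fam_members: Dict[str, List[Tuple[str, str]]] = {}
    for g in sorted(proteomes.proteins):
        for gid in sorted(proteomes.proteins[g]):
            fam = gid.split("_", 1)[1]
            fam_members.setdefault(fam, []).append((g, gid))
    edges = []
    for fam, mem in sorted(fam_members.items()):
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                (ga, ia), (gb, ib) = mem[i], mem[j]
                sa, sb = proteomes.proteins[ga][ia], proteomes.proteins[gb][ib]
                n = min(len(sa), len(sb))
                ident = 100.0 * sum(x == y for x, y in zip(sa, sb)) / n
                edges.append(SimilarityEdge(
                    query_id=f"{ga}|{ia}", subject_id=f"{gb}|{ib}",
                    pct_identity=ident, aligned_len=n, evalue=1e-50,
                    bitscore=2.0 * n * ident / 100.0))
    return edges, lengths
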