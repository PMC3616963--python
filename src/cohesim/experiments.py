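"""Simulation experiments that exercise the full analysis end to end.

Each function sets up one study condition on the bundled two-clade
species tree, runs the relevant pipeline stage(s), and returns summary
numbers.  These are the single source of truth for the analysis drivers,
the test suite and the acceptance script, so the conditions are defined
once.

Problem sizes default to desk scale (hundreds of genes of ~1 kb); the
per-gene random seeds are all derived from the experiment seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import divergence, phylo, recomb, seqsim
from .seqsim import SimParams, SpeciesTree, default_species_tree

GROUP_A = ["wHa", "wMel", "wRi"]
GROUP_B = ["wAlbB", "wNo", "wPip"]


def _gene_seed(seed: int, index: int) -> int:
    """Stable sub-seed below 2^31 for gene ``index`` of an experiment."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]
               % (2 ** 31))


def _simulate_census_gene(species: SpeciesTree, mode: str, seed: int,
                          seq_length: int) -> seqsim.SimulatedGene:
    params = SimParams(seq_length=seq_length, seed=seed)
    if mode == "clonal":
        return seqsim.simulate_gene(species, params)
    if mode == "randomized":
        rng = np.random.default_rng([seed, 6])
        gt = seqsim.sample_gene_tree(species, rng, randomize_topology=True)
        return seqsim.simulate_gene_on_tree(gt, species, params)
    raise ValueError(f"unknown mode {mode!r}")


# -- topology census --------------------------------------------------------

@dataclass
class CensusSummary:
    census: phylo.CensusResult
    generating_class_pct: float
    split_retained_pct: float
    within_a_pct: Dict[str, float]
    within_b_pct: Dict[str, float]


def census_experiment(n_genes: int = 300, mode: str = "clonal",
                      seed: int = 0, seq_length: int = 1002,
                      refine_top: int = 5) -> CensusSummary:
    """Gene-tree census over simulated genes.

    ``mode='clonal'`` evolves every gene on the species tree;
    ``mode='randomized'`` redraws each gene's within-clade history (the
    free within-clade recombination limit).  Trees come from the
    exhaustive ML search with least-squares ranking and refinement of the
    leading ``refine_top`` topologies.
    """
    species = default_species_tree()
    trees = []
    for g in range(n_genes):
        gene = _simulate_census_gene(species, mode, _gene_seed(seed, g),
                                     seq_length)
        res = phylo.exhaustive_ml_search(gene.sequences(),
                                         refine_top=refine_top,
                                         sweeps=1, xatol=1e-4)
        trees.append(res.best)
    census = phylo.topology_census(trees, GROUP_A, GROUP_B)
    generating = (phylo._pair_key("wRi", "wHa"),
                  phylo._pair_key("wPip", "wAlbB"))
    n = census.n_considered
    gen_pct = 100.0 * census.counts.get(generating, 0) / n
    split_pct = 100.0 * census.split_respecting() / n
    within_a: Dict[str, float] = {}
    within_b: Dict[str, float] = {}
    for (ra, rb), cnt in census.counts.items():
        within_a[ra] = within_a.get(ra, 0) + cnt
        within_b[rb] = within_b.get(rb, 0) + cnt
    denom_a = max(sum(within_a.values()), 1)
    within_a = {k: 100.0 * v / denom_a for k, v in sorted(within_a.items())}
    denom_b = max(sum(within_b.values()), 1)
    within_b = {k: 100.0 * v / denom_b for k, v in sorted(within_b.items())}
    return CensusSummary(census, gen_pct, split_pct, within_a, within_b)


# -- relative-dS spread -----------------------------------------------------

def _trio_ds(gene: seqsim.SimulatedGene, trio: Sequence[str]) -> List[float]:
    seqs = gene.sequences()
    trio = sorted(trio)
    out = []
    for i in range(3):
        for j in range(i + 1, 3):
            d = divergence.estimate_dn_ds(seqs[trio[i]], seqs[trio[j]],
                                          pair=(trio[i], trio[j]),
                                          on_bad_codon="drop")
            out.append(d.dS)
    return out


def spread_experiment(n_genes: int = 200, mode: str = "clonal",
                      seed: int = 0, seq_length: int = 999,
                      trio: Optional[Sequence[str]] = None) -> float:
    """Ternary spread of relative dS over simulated genes for one trio.

    Codon-aware simulation; pairwise dS by Nei-Gojobori counting.  Genes
    whose dS triple is undefined (saturated or all-zero) are skipped, as
    in the real analysis.
    """
    trio = sorted(trio) if trio is not None else ["wHa", "wMel", "wRi"]
    species = default_species_tree()
    per_gene: List[Tuple[str, List[float]]] = []
    for g in range(n_genes):
        gene_seed = _gene_seed(seed, g)
        params = SimParams(seq_length=seq_length, seed=gene_seed)
        if mode == "clonal":
            gene = seqsim.simulate_gene(species, params, codon_aware=True)
        else:
            rng = np.random.default_rng([gene_seed, 6])
            gt = seqsim.sample_gene_tree(species, rng,
                                         randomize_topology=True)
            gene = seqsim.simulate_gene_on_tree(gt, species, params,
                                                codon_aware=True)
        ds = _trio_ds(gene, trio)
        if any(np.isnan(v) for v in ds) or sum(ds) <= 0:
            continue
        per_gene.append((f"gene{g:04d}", ds))
    points = divergence.collect_ternary_points(per_gene)
    return divergence.spread(points)


# -- detector battery, calibration and power --------------------------------

MAXCHI_WINDOW = 70   # polymorphic columns per half-window


def detector_battery(seqs: Dict[str, str], seed: int, n_perm: int = 1000,
                     geneconv_perm: int = 2000,
                     gscale: float = 1.0,
                     maxchi_window: Optional[int] = MAXCHI_WINDOW
                     ) -> Tuple[Dict[str, float], List[recomb.Fragment]]:
    """Run all four detectors on one gene with per-method sub-seeds.

    Returns ({Phi, NSS, MaxChi p-values}, gene-conversion fragments); the
    gene-conversion method counts as significant iff fragments is
    non-empty (its own Bonferroni KA < 0.05 rule).
    """
    ps = {
        "Phi": recomb.phi_test(seqs, n_perm=n_perm,
                               seed=_gene_seed(seed, 10)),
        "NSS": recomb.nss_test(seqs, n_perm=n_perm,
                               seed=_gene_seed(seed, 11)),
        "MaxChi": recomb.maxchi_test(seqs, window=maxchi_window,
                                     n_perm=n_perm,
                                     seed=_gene_seed(seed, 12))[0],
    }
    frags, _ = recomb.geneconv_fragments(seqs, gscale=gscale,
                                         n_perm=geneconv_perm,
                                         seed=_gene_seed(seed, 13))
    return ps, frags


@dataclass
class CalibrationSummary:
    n_genes: int
    alpha: float
    type1: Dict[str, float]          # empirical rejection rate per detector
    n_tested: Dict[str, int]         # genes with a defined p-value


def detector_calibration(n_genes: int = 500, seed: int = 0,
                         seq_length: int = 1002, n_perm: int = 1000,
                         alpha: float = 0.01) -> CalibrationSummary:
    """Empirical type-I error of the detectors on clonal genes.

    Phi/NSS/MaxChi are judged at ``alpha``; the gene-conversion method at
    its own Bonferroni KA < 0.05 fragment rule (reported alongside).
    """
    species = default_species_tree()
    reject = {"Phi": 0, "NSS": 0, "MaxChi": 0, "GENECONV": 0}
    tested = {"Phi": 0, "NSS": 0, "MaxChi": 0, "GENECONV": 0}
    for g in range(n_genes):
        gene_seed = _gene_seed(seed, g)
        gene = seqsim.simulate_gene(
            species, SimParams(seq_length=seq_length, seed=gene_seed))
        ps, frags = detector_battery(gene.sequences(), gene_seed,
                                     n_perm=n_perm, geneconv_perm=n_perm)
        for k, p in ps.items():
            if not np.isnan(p):
                tested[k] += 1
                if p < alpha:
                    reject[k] += 1
        tested["GENECONV"] += 1
        reject["GENECONV"] += bool(frags)
    rates = {k: reject[k] / tested[k] if tested[k] else float("nan")
             for k in reject}
    return CalibrationSummary(n_genes, alpha, rates, tested)


def detector_power(n_genes: int = 100, tract_length: int = 500,
                   seed: int = 0, seq_length: int = 1002,
                   n_perm: int = 1000, alpha: float = 0.01,
                   kind: str = "within") -> Dict[str, float]:
    """Detection power for one planted tract of fixed length per gene.

    The donor/recipient pair is drawn uniformly within a clade (or across
    clades for ``kind='between'``) among the sampled strains; the tract
    position is uniform among positions where the full tract fits.
    Returns per-method powers plus ``battery`` — the fraction of genes
    where at least one of the four methods detects the event, which is
    how a gene counts as recombination-positive in the analysis.
    """
    species = default_species_tree()
    reject = {"Phi": 0, "NSS": 0, "MaxChi": 0, "GENECONV": 0, "battery": 0}
    for g in range(n_genes):
        gene_seed = _gene_seed(seed, g)
        rng = np.random.default_rng([gene_seed, 7])
        params = SimParams(seq_length=seq_length, seed=gene_seed)
        gene = seqsim.simulate_gene(species, params)
        recipient = str(rng.choice(gene.labels))
        grp = species.clade_map[recipient]
        if kind == "within":
            pool = [l for l in gene.labels
                    if species.clade_map[l] == grp and l != recipient]
        else:
            pool = [l for l in gene.labels if species.clade_map[l] != grp]
        donor = str(rng.choice(pool))
        start = int(rng.integers(1, seq_length - tract_length + 2))
        gene = seqsim.plant_tract(gene, species, params, donor, recipient,
                                  start, start + tract_length - 1)
        ps, frags = detector_battery(gene.sequences(), gene_seed,
                                     n_perm=n_perm)
        any_hit = bool(frags)
        for k, p in ps.items():
            if not np.isnan(p) and p < alpha:
                reject[k] += 1
                any_hit = True
        reject["GENECONV"] += bool(frags)
        reject["battery"] += any_hit
    return {k: v / n_genes for k, v in reject.items()}


# -- fragment-size contrast -------------------------------------------------

def fragment_contrast(n_genes: int = 60, seed: int = 0,
                      seq_length: int = 1002,
                      gscales: Sequence[float] = (0.0, 1.0, 3.0),
                      n_perm: int = 2000,
                      tract_mean_within: float = 500.0,
                      tract_mean_between: float = 120.0
                      ) -> Dict[float, Dict[str, float]]:
    """Median detected fragment length: within-clade vs between-clade
    planted tracts, per gscale.

    Each condition plants one geometric-length tract per gene (means per
    the within/between contrast) and collects the significant
    gene-conversion fragments attributed to pairs of the planted kind.
    """
    species = default_species_tree()
    groups = dict(species.clade_map)
    lengths: Dict[Tuple[float, str], List[int]] = {}
    for cond, mean in (("within", tract_mean_within),
                       ("between", tract_mean_between)):
        for g in range(n_genes):
            gene_seed = _gene_seed(seed, g if cond == "within"
                                   else g + n_genes)
            rng = np.random.default_rng([gene_seed, 8])
            params = SimParams(seq_length=seq_length, seed=gene_seed)
            gene = seqsim.simulate_gene(species, params)
            recipient = str(rng.choice(gene.labels))
            grp = species.clade_map[recipient]
            if cond == "within":
                pool = [l for l in gene.labels
                        if species.clade_map[l] == grp and l != recipient]
            else:
                pool = [l for l in gene.labels
                        if species.clade_map[l] != grp]
            donor = str(rng.choice(pool))
            tract = min(int(rng.geometric(1.0 / mean)), seq_length)
            start = int(rng.integers(1, seq_length - tract + 2))
            gene = seqsim.plant_tract(gene, species, params, donor,
                                      recipient, start, start + tract - 1)
            seqs = gene.sequences()
            for gscale in gscales:
                frags, _ = recomb.geneconv_fragments(
                    seqs, gscale=gscale, n_perm=n_perm,
                    seed=_gene_seed(gene_seed, 13))
                annotated, _ = recomb.classify_fragments(frags, groups)
                want = ("between",) if cond == "between" else (
                    "within_A", "within_B")
                for f in annotated:
                    if f.frag_class in want:
                        lengths.setdefault((gscale, cond), []).append(
                            f.length)
    out: Dict[float, Dict[str, float]] = {}
    for gscale in gscales:
        entry = {}
        for cond in ("within", "between"):
            vals = lengths.get((gscale, cond), [])
            entry[f"median_{cond}_bp"] = (float(np.median(vals))
                                          if vals else float("nan"))
            entry[f"n_{cond}"] = float(len(vals))
        out[gscale] = entry
    return out


# -- r/m post-processing ----------------------------------------------------

def rm_reference_track(n_mut_sites: int = 481, n_rec_sites: int = 4243,
                       filler: int = 500) -> recomb.PosteriorTrack:
    """A posterior track constructed to contain exactly the given numbers
    of mutation- and recombination-qualifying sites.

    Qualifying mutation sites have S = 1, R = 0; recombination sites sit
    inside one plateau with R = 0.96, S = 1; filler sites qualify as
    neither (S = 0.3, R = 0.3 is below both products and below the event
    run floor... the run floor is 0.5, so filler also breaks event runs).
    """
    n = n_mut_sites + n_rec_sites + 2 * filler
    s = np.full(n, 0.3)
    r = np.full(n, 0.3)
    s[:n_mut_sites] = 1.0
    r[:n_mut_sites] = 0.0
    start = n_mut_sites + filler
    s[start: start + n_rec_sites] = 1.0
    r[start: start + n_rec_sites] = 0.96
    return recomb.PosteriorTrack(S=s, R=r)


# -- group-specific gene recovery -------------------------------------------

@dataclass
class SpecificRecovery:
    planted: Dict[str, int]
    called: Dict[str, int]
    exact: bool
    n_core_recovered: int


def specific_recovery(seed: int = 0, n_core: int = 20,
                      n_specific_per_group: Tuple[int, int] = (33, 24),
                      pseudogene_fraction: float = 0.25,
                      inflation: float = 1.5) -> SpecificRecovery:
    """Round-trip a planted proteome fixture through orthology and
    clade-specific calling: similarity edges -> homology filter -> MCL ->
    single-copy clusters -> presence calls -> specific-gene census."""
    from . import genecontent, orthology

    prot = seqsim.simulate_proteomes(
        n_core=n_core, n_specific_per_group=n_specific_per_group,
        pseudogene_fraction=pseudogene_fraction, seed=seed)
    edges, lengths = seqsim.truth_similarity_edges(prot)
    kept = orthology.filter_edges(edges, lengths)
    node_ids, adj = orthology.build_graph(kept, nodes=sorted(lengths))
    clusters = orthology.mcl_cluster(node_ids, adj, inflation=inflation)
    genomes = sorted(prot.groups)
    core = orthology.extract_single_copy_core(clusters, genomes)

    def family_of(cluster) -> str:
        gene = cluster.members[0].split("|", 1)[1]
        return gene.split("_", 1)[1]

    hits = seqsim.truth_search_hits(prot, seed=seed)
    named = [(family_of(c), c) for c in clusters]
    presence = {}
    for fam, per_genome in hits.items():
        for genome, hs in per_genome.items():
            presence[(fam, genome)] = genecontent.call_presence(hs)
    calls, counts = genecontent.call_group_specific(
        named, presence, prot.groups)
    planted = {"A": sum(1 for _, cls, _ in prot.truth
                        if cls == "A_specific"),
               "B": sum(1 for _, cls, _ in prot.truth
                        if cls == "B_specific")}
    exact = counts.get("A", 0) == planted["A"] \
        and counts.get("B", 0) == planted["B"]
    return SpecificRecovery(planted, dict(counts), exact, len(core))
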