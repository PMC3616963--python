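"""Sequence simulator: determinism, stationarity, tract bookkeeping."""

import numpy as np
import pytest
from scipy.stats import chisquare

from cohesim import seqsim
from cohesim.seqsim import (SimParams, SpeciesTree, default_species_tree,
                            simulate_gene, simulate_posterior_track,
                            simulate_proteomes)
from cohesim.trees import parse_newick


def two_taxon_species(length):
    t = parse_newick(f"(a:{length},b:{length});")
    return SpeciesTree(t, {"a": "A", "b": "B"})


def test_same_seed_is_bitwise_identical(species):
    p = SimParams(seq_length=600, seed=7)
    g1 = simulate_gene(species, p)
    g2 = simulate_gene(species, p)
    assert np.array_equal(g1.states, g2.states)
    assert g1.labels == g2.labels
    g3 = simulate_gene(species, SimParams(seq_length=600, seed=8))
    assert not np.array_equal(g1.states, g3.states)


def test_zero_branch_lengths_give_identical_rows():
    sp = two_taxon_species(0.0)
    g = simulate_gene(sp, SimParams(seq_length=500, seed=1))
    assert np.array_equal(g.states[0], g.states[1])


def test_saturation_limit_pairwise_identity_quarter():
    # branch length -> infinity with equal frequencies: identity -> 0.25
    sp = two_taxon_species(20.0)
    p = SimParams(seq_length=100_000, seed=3,
                  base_freqs=np.full(4, 0.25))
    g = simulate_gene(sp, p)
    identity = float((g.states[0] == g.states[1]).mean())
    assert identity == pytest.approx(0.25, abs=0.01)


def test_long_simulation_matches_stationary_frequencies():
    sp = two_taxon_species(0.5)
    p = SimParams(seq_length=100_000, seed=4)
    g = simulate_gene(sp, p)
    counts = np.bincount(g.states.ravel(), minlength=4)
    expected = p.base_freqs * counts.sum()
    assert chisquare(counts, expected).pvalue > 0.01


def test_invalid_rate_matrix_rejected():
    with pytest.raises(ValueError):
        SimParams(gtr_rates=np.array([1.0, -1.0, 1.0, 1.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        SimParams(base_freqs=np.array([0.5, 0.5, 0.1, 0.1]))
    with pytest.raises(ValueError):
        SimParams(tract_mean_within=0.5)


def test_codon_aware_rows_are_stop_free(species):
    g = simulate_gene(species, SimParams(seq_length=999, seed=5),
                      codon_aware=True)
    for seq in g.sequences().values():
        prot_codons = [seq[k:k + 3] for k in range(0, len(seq), 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in prot_codons)


def test_zero_rates_leave_gene_unchanged(species):
    p = SimParams(seq_length=400, seed=6)
    g = simulate_gene(species, p)
    g2 = seqsim.apply_recombination(g, species, p)
    assert np.array_equal(g.states, g2.states)
    assert g2.truth_log == []


def test_tract_length_distribution_matches_geometric_mean(species):
    # law of large numbers on the geometric tract length
    lengths = []
    for seed in range(400):
        p = SimParams(seq_length=20_000, seed=seed, rec_rate_within=5,
                      tract_mean_within=500.0)
        g = simulate_gene(species, SimParams(seq_length=20_000, seed=seed))
        g = seqsim.apply_recombination(g, species, p)
        lengths.extend(ev.end - ev.start + 1 for ev in g.truth_log
                       if ev.kind == "within")
    assert len(lengths) > 1500
    assert np.mean(lengths) == pytest.approx(500.0, rel=0.05)


def test_tract_log_records_coordinates_and_kinds(species):
    p = SimParams(seq_length=900, seed=11, rec_rate_within=2,
                  rec_rate_between=2)
    g = seqsim.apply_recombination(simulate_gene(species, p), species, p)
    assert g.truth_log
    for ev in g.truth_log:
        assert 1 <= ev.start <= ev.end <= 900
        assert ev.kind in ("within", "between")
        same = (species.clade_map[ev.donor] == species.clade_map[ev.recipient])
        assert same == (ev.kind == "within")


def test_whole_gene_between_tract_breaks_the_deep_split(species):
    # downstream check: a between-clade tract covering the whole gene
    # makes the ML tree violate the two-clade separation
    from cohesim import phylo

    p = SimParams(seq_length=1002, seed=12)
    g = simulate_gene(species, p)
    g = seqsim.plant_tract(g, species, p, donor="wNo", recipient="wMel",
                           start=1, end=1002)
    res = phylo.exhaustive_ml_search(g.sequences(), refine_top=5, sweeps=1,
                                     xatol=1e-4)
    assert not res.best.has_split(("wHa", "wMel", "wRi"))


def test_sample_gene_tree_keeps_split_and_randomizes_resolution(species):
    rng = np.random.default_rng(0)
    cherries = set()
    for _ in range(40):
        t = seqsim.sample_gene_tree(species, rng)
        assert t.has_split(("wHa", "wMel", "wRi"))
        for pair in (("wHa", "wMel"), ("wHa", "wRi"), ("wMel", "wRi")):
            if t.has_split(pair):
                cherries.add(pair)
    assert len(cherries) == 3


# -- posterior tracks -------------------------------------------------------

def test_track_no_events_background_zero():
    tr = simulate_posterior_track(50, [], background_R=0.0)
    assert np.all(tr.R == 0.0)


def test_track_plateau_and_event_counting():
    from cohesim.recomb import count_events

    tr = simulate_posterior_track(100, [(10, 20, 0.96)], background_R=0.1)
    assert count_events(tr) == 1
    low = simulate_posterior_track(100, [(10, 20, 0.80)], background_R=0.1)
    assert count_events(low) == 0


def test_track_rejects_overlap_and_bad_bounds():
    with pytest.raises(ValueError):
        simulate_posterior_track(100, [(10, 30, 0.9), (25, 40, 0.9)],
                                 background_R=0.0)
    with pytest.raises(ValueError):
        simulate_posterior_track(100, [(90, 110, 0.9)], background_R=0.0)
    with pytest.raises(ValueError):
        simulate_posterior_track(100, [(10, 20, 1.5)], background_R=0.0)


# -- proteomes --------------------------------------------------------------

def test_proteomes_plant_core_and_specific_families():
    prot = simulate_proteomes(n_core=5, n_specific_per_group=(3, 2),
                              pseudogene_fraction=1.0, seed=1)
    genomes = sorted(prot.groups)
    core = [f for f, cls, _ in prot.truth if cls == "core"]
    assert len(core) == 5
    for fam in core:
        for g in genomes:
            assert sum(1 for gid in prot.proteins[g]
                       if gid.endswith(fam)) == 1
    a_spec = [row for row in prot.truth if row[1] == "A_specific"]
    assert len(a_spec) == 3
    b_genomes = [g for g, lab in prot.groups.items() if lab == "B"]
    for fam, _, remnant_in in a_spec:
        # pseudogene_fraction = 1: every A-specific family leaves a
        # disrupted remnant in every B genome
        assert set(remnant_in) == set(b_genomes)
        for g in b_genomes:
            assert not any(gid.endswith(fam) for gid in prot.proteins[g])
            assert (fam, g) in prot.pseudogene_cds


def test_proteome_cds_translate_to_proteins():
    from Bio.Seq import Seq

    prot = simulate_proteomes(n_core=3, n_specific_per_group=(1, 1), seed=2)
    for g in prot.proteins:
        for gid, aa in prot.proteins[g].items():
            assert str(Seq(prot.cds[g][gid]).translate(table=11)) == aa
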