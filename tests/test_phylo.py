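"""Likelihood core vs brute-force oracle, tree fitting, search, census."""

import itertools

import numpy as np
import pytest

from cohesim import phylo, seqsim
from cohesim.gtr import GTRParams, rate_matrix, transition_matrices, \
    eigendecompose
from cohesim.phylo import (empirical_params, exhaustive_ml_search, fit_tree,
                           log_likelihood, topology_census)
from cohesim.seqsim import SimParams, SpeciesTree, simulate_gene
from cohesim.trees import enumerate_topologies, parse_newick


def brute_force_loglik(seqs, tree, params):
    """Independent oracle: explicit sum over internal-node states."""
    labels = sorted(seqs)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    lam, u, v = eigendecompose(params)
    rates = params.rate_categories()
    internal = [n for n in range(tree.n_nodes())
                if tree.label[n] is None]
    leaf_nodes = {lab: tree.find_leaf(lab) for lab in labels}
    n_sites = len(seqs[labels[0]])
    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for ci, r in enumerate(rates):
            P = {n: transition_matrices(lam, u, v,
                                        np.array([tree.length[n]]),
                                        np.array([r]))[0, 0]
                 for n in range(tree.n_nodes())}
            lik = 0.0
            for states in itertools.product(range(4), repeat=len(internal)):
                assign = dict(zip(internal, states))
                for lab in labels:
                    ch = seqs[lab][site]
                    assign[leaf_nodes[lab]] = idx.get(ch)
                term = params.base_freqs[assign[tree.root]]
                ok = True
                for n in range(tree.n_nodes()):
                    if n == tree.root:
                        continue
                    if assign[n] is None:      # gap: marginalise later
                        ok = False
                        break
                    term *= P[n][assign[tree.parent[n]], assign[n]]
                if ok:
                    lik += term
            site_lik += lik
        total += np.log(site_lik / len(rates))
    return total


def test_two_taxa_single_site_stationarity():
    t = parse_newick("(a:0,b:0);")
    ll = log_likelihood({"a": "A", "b": "A"}, t, GTRParams())
    assert ll == pytest.approx(np.log(0.25))


@pytest.mark.parametrize("gamma_shape", [None, 0.7])
def test_pruning_equals_brute_force_on_four_taxa(gamma_shape):
    rng = np.random.default_rng(0)
    params = GTRParams(np.array([1.0, 3.0, 1.0, 1.0, 3.0, 1.0]),
                       np.array([0.3, 0.2, 0.2, 0.3]), gamma_shape)
    for t in enumerate_topologies(list("abcd")):
        for n in range(t.n_nodes()):
            t.length[n] = float(rng.uniform(0.01, 0.8))
        seqs = {lab: "".join(rng.choice(list("ACGT"), size=20))
                for lab in "abcd"}
        fast = log_likelihood(seqs, t, params)
        slow = brute_force_loglik(seqs, t, params)
        assert fast == pytest.approx(slow, abs=1e-8)


def test_duplicated_columns_double_the_loglik():
    rng = np.random.default_rng(1)
    t = enumerate_topologies(list("abcd"))[1]
    seqs = {lab: "".join(rng.choice(list("ACGT"), size=30))
            for lab in "abcd"}
    doubled = {k: v + v for k, v in seqs.items()}
    p = GTRParams()
    assert log_likelihood(doubled, t, p) == pytest.approx(
        2 * log_likelihood(seqs, t, p))


def test_gaps_are_missing_data():
    t = parse_newick("(a:0.1,b:0.1);")
    p = GTRParams()
    with_gap = log_likelihood({"a": "A-", "b": "AC"}, t, p)
    without = log_likelihood({"a": "A", "b": "A"}, t, p)
    # the gapped column contributes the marginal of 'C' alone = pi_C
    assert with_gap == pytest.approx(without + np.log(0.25))


def test_label_mismatch_rejected(clonal_seqs):
    t = parse_newick("(a:1,(b:1,c:1):1,d:1);")
    with pytest.raises(ValueError):
        log_likelihood(clonal_seqs, t, GTRParams())


def test_fit_tree_never_decreases_loglik_and_recovers_lengths(species):
    gene = simulate_gene(species, SimParams(seq_length=20_001, seed=21))
    seqs = gene.sequences()
    p0 = empirical_params(seqs)
    t0 = species.tree.copy()
    for n in range(t0.n_nodes()):
        if n != t0.root:
            t0.length[n] = 0.05
    ll_init = log_likelihood(seqs, t0, p0)
    fitted, params, ll = fit_tree(seqs, t0, p0, optimize_model=True)
    assert ll >= ll_init
    # branch lengths recovered within 15% on 10 kb
    true_b = species.tree.bipartitions(with_trivial=True)
    fit_b = fitted.bipartitions(with_trivial=True)
    for split, tv in true_b.items():
        if tv >= 0.02:
            assert fit_b[split] == pytest.approx(tv, rel=0.15)
        elif tv > 0.005:
            # short branches carry few substitutions: wider tolerance
            assert fit_b[split] == pytest.approx(tv, rel=0.25)


def test_zero_length_true_branch_estimated_near_zero():
    # hard polytomy: the internal branch joining (a,b) has length 0.
    # Homoplasy adds a stray supporting site now and then, so the check
    # is on the median across seeds.
    t = parse_newick("((a:0.003,b:0.003):0.0,c:0.003,d:0.05);")
    sp = SpeciesTree(t, {"a": "A", "b": "A", "c": "A", "d": "B"})
    estimates = []
    for seed in (3, 4, 5):
        gene = simulate_gene(sp, SimParams(seq_length=20_000, seed=seed))
        fitted, _, _ = fit_tree(gene.sequences(), t, empirical_params(
            gene.sequences()), optimize_model=False)
        internal = next(n for n in range(fitted.n_nodes())
                        if fitted.label[n] is None and n != fitted.root)
        estimates.append(fitted.length[internal])
    assert np.median(estimates) <= 1e-4


def test_all_missing_row_rejected():
    t = parse_newick("(a:1,(b:1,c:1):1,d:1);")
    seqs = {"a": "ACGT", "b": "ACGT", "c": "ACGT", "d": "----"}
    with pytest.raises(ValueError):
        fit_tree(seqs, t, GTRParams())


def test_exhaustive_search_enumerates_and_guards():
    gene_seqs = {lab: "ACGTACGTACGT" for lab in "abcdef"}
    res = exhaustive_ml_search(gene_seqs, refine_top=1)
    assert res.n_topologies == 105
    too_many = {f"t{i}": "ACGT" for i in range(9)}
    with pytest.raises(ValueError):
        exhaustive_ml_search(too_many)


def test_search_recovers_generating_topology(species):
    hits = 0
    n = 30
    for seed in range(n):
        gene = simulate_gene(species, SimParams(seq_length=2001, seed=seed))
        res = exhaustive_ml_search(gene.sequences(), refine_top=5, sweeps=1,
                                   xatol=1e-4)
        hits += res.best.topology_key() == species.tree.topology_key()
    assert hits >= int(0.9 * n)


def test_four_taxon_search_matches_clean_distance_tree():
    t = parse_newick("((a:0.05,b:0.05):0.1,c:0.05,d:0.15);")
    sp = SpeciesTree(t, {"a": "A", "b": "A", "c": "B", "d": "B"})
    gene = simulate_gene(sp, SimParams(seq_length=5001, seed=9))
    res = exhaustive_ml_search(gene.sequences())
    assert res.best.has_split(("a", "b"))


def test_bootstrap_support_bounds_and_degenerate_input(species):
    gene = simulate_gene(species, SimParams(seq_length=5001, seed=13))
    seqs = gene.sequences()
    res = exhaustive_ml_search(seqs, refine_top=3, sweeps=1, xatol=1e-4)
    out = phylo.bootstrap_support(seqs, res.best, n_reps=30, seed=5)
    sup = [s for s in out.support if s is not None]
    assert sup and all(0.0 <= s <= 100.0 for s in sup)
    assert min(sup) >= 90.0        # 5 kb clonal: all true edges strong
    flat = {lab: "ACGT" * 30 for lab in sorted(seqs)}
    star = phylo.bootstrap_support(flat, res.best, n_reps=5, seed=5)
    assert all(s == 0.0 for s in star.support if s is not None)


# -- census -----------------------------------------------------------------

A = ["a1", "a2", "a3"]
B = ["b1", "b2", "b3"]


def class_tree(pa, pb, split=True):
    """Build a 6-leaf tree with given within-group cherries."""
    a3 = next(x for x in A if x not in pa)
    b3 = next(x for x in B if x not in pb)
    if split:
        nwk = (f"(({pa[0]}:1,{pa[1]}:1):1,{a3}:1,"
               f"(({pb[0]}:1,{pb[1]}:1):1,{b3}:1):1);")
    else:
        nwk = (f"(({pa[0]}:1,{pb[0]}:1):1,{pa[1]}:1,"
               f"(({a3}:1,{pb[1]}:1):1,{b3}:1):1);")
    return parse_newick(nwk)


def test_census_classifies_forced_examples():
    t = class_tree(("a1", "a2"), ("b1", "b2"))
    res = topology_census([t], A, B)
    assert res.counts[("a1+a2", "b1+b2")] == 1
    assert res.incongruent == 0
    bad = class_tree(("a1", "a2"), ("b1", "b2"), split=False)
    res2 = topology_census([bad], A, B)
    assert res2.incongruent == 1


def test_census_covers_all_nine_classes():
    pairs_a = [("a1", "a2"), ("a1", "a3"), ("a2", "a3")]
    pairs_b = [("b1", "b2"), ("b1", "b3"), ("b2", "b3")]
    trees = [class_tree(pa, pb) for pa in pairs_a for pb in pairs_b]
    res = topology_census(trees, A, B)
    assert sorted(res.counts.values()) == [1] * 9
    assert res.incongruent == 0
    assert res.split_respecting() + res.incongruent == len(trees)


def test_census_support_floor_is_strict():
    t = class_tree(("a1", "a2"), ("b1", "b2"))
    for n in range(t.n_nodes()):
        if t.label[n] is None and n != t.root:
            t.support[n] = 75.0       # exactly at the floor: excluded
    res = topology_census([t], A, B, support_floor=75.0)
    assert res.n_filtered_out == 1
    for n in range(t.n_nodes()):
        if t.label[n] is None and n != t.root:
            t.support[n] = 76.0
    res2 = topology_census([t], A, B, support_floor=75.0)
    assert res2.n_filtered_out == 0
    assert res2.counts[("a1+a2", "b1+b2")] == 1
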