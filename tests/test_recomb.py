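"""Recombination detectors, fragments, and posterior-track post-processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohesim import recomb
from cohesim.recomb import (Fragment, PosteriorTrack, classify_fragments,
                            count_events, ensemble_vote, geneconv_fragments,
                            maxchi_test, nss_test, phi_test, rm_counts)


def test_phi_undefined_below_two_informative_sites():
    seqs = {"a": "AAAA", "b": "AAAA", "c": "AAAT", "d": "AAAT"}
    # one informative site only
    assert np.isnan(phi_test(seqs, n_perm=50, seed=0))


def test_phi_and_nss_detect_constructed_mosaic(mosaic_seqs):
    assert phi_test(mosaic_seqs, n_perm=500, seed=1) < 0.01
    assert nss_test(mosaic_seqs, n_perm=500, seed=1) < 0.01
    p, _ = maxchi_test(mosaic_seqs, n_perm=500, seed=1)
    assert p < 0.01


def test_clonal_gene_not_flagged(clonal_seqs):
    assert phi_test(clonal_seqs, n_perm=300, seed=2) > 0.01
    assert nss_test(clonal_seqs, n_perm=300, seed=2) > 0.01


def test_nss_perfectly_compatible_data_not_significant():
    # two clean blocks of identical binary signal: all sites compatible
    seqs = {"a": "AAAAAA", "b": "AAAAAA", "c": "TTTTTT", "d": "TTTTTT"}
    p = nss_test(seqs, n_perm=200, seed=0)
    assert p > 0.5


def test_permutation_p_respects_addone_bound(mosaic_seqs):
    n_perm = 99
    for fn in (phi_test, nss_test):
        p = fn(mosaic_seqs, n_perm=n_perm, seed=3)
        assert 1.0 / (n_perm + 1) <= p <= 1.0


def test_maxchi_identical_sequences_stat_zero_p_one():
    seqs = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}
    p, best = maxchi_test(seqs, n_perm=100, seed=0)
    assert p == 1.0 and best == {}


def test_maxchi_toy_breakpoint_and_chi2():
    # half-divergent pair; a third sequence keeps all 12 columns variable
    seqs = {"a": "AAAAAATTTTTT", "b": "AAAAAAAAAAAA", "c": "CCCCCCCCCCCC"}
    p, best = maxchi_test(seqs, n_perm=200, seed=1)
    bp, chi2 = best[("a", "b")]
    assert bp == 7                     # breakpoint between sites 6 and 7
    assert chi2 == pytest.approx(12.0)


def test_geneconv_identical_pair_spans_all_polymorphic_sites():
    seqs = {
        "a": "ACGTACGTACGTACGTACGT",
        "b": "ACGTACGTACGTACGTACGT",
        "c": "GTACGTACGTACGTACGTAC",
        "d": "TGCATGCATGCATGCATGCA",
    }
    # a fully matching pair has a degenerate permutation null (ka_p = 1);
    # alpha above 1 exposes the candidate fragment itself
    frags, p = geneconv_fragments(seqs, gscale=1.0, n_perm=500, seed=0,
                                  alpha=1.1)
    ab = [f for f in frags if f.pair == ("a", "b")]
    assert ab
    top = ab[0]
    assert top.start == 1 and top.end == 20
    assert top.score == pytest.approx(20.0)


def test_geneconv_gscale_zero_mismatch_splits_fragment():
    a = "A" * 10 + "C" + "A" * 10
    b = "A" * 21
    filler1 = "G" * 21
    filler2 = "T" * 21
    seqs = {"a": a, "b": b, "c": filler1, "d": filler2}
    frags, _ = geneconv_fragments(seqs, gscale=0.0, n_perm=500, seed=0,
                                  alpha=1.1)
    ab = sorted((f.start, f.end) for f in frags if f.pair == ("a", "b"))
    assert ab == [(1, 10), (12, 21)]


def test_geneconv_needs_three_sequences_and_handles_monomorphic():
    with pytest.raises(ValueError):
        geneconv_fragments({"a": "ACGT", "b": "ACGT"})
    frags, p = geneconv_fragments({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
    assert frags == [] and p == 1.0


def test_ensemble_vote_tiers():
    assert ensemble_vote({"NSS": 0.001, "MaxChi": 0.005, "Phi": 0.0001},
                         geneconv_pass=True) == 4
    assert ensemble_vote({"NSS": 0.05, "MaxChi": 0.005, "Phi": 0.0001},
                         geneconv_pass=True) == 3
    nan = float("nan")
    assert ensemble_vote({"NSS": nan, "MaxChi": nan, "Phi": nan},
                         geneconv_pass=False) == 0


def frag(pair, start=10, end=100, **kw):
    return Fragment(pair=pair, start=start, end=end, score=10.0,
                    ka_p=0.01, **kw)


def test_classify_fragments_by_group():
    groups = {"wRi": "A", "wHa": "A", "wNo": "B", "wPip": "B"}
    frags = [frag(("wRi", "wHa")), frag(("wHa", "wNo")),
             frag(("wNo", "wPip"), start=1, end=50)]
    out, summaries = classify_fragments(frags, groups)
    assert [f.frag_class for f in out] == ["within_A", "between", "within_B"]
    assert summaries[("within_A", 1.0)]["median"] == 91
    assert summaries[("within_B", 1.0)]["n"] == 1
    empty, s_empty = classify_fragments([], groups)
    assert empty == [] and s_empty == {}


def test_classify_rejects_unlabelled_genome():
    with pytest.raises(KeyError, match="wX"):
        classify_fragments([frag(("wX", "wHa"))], {"wHa": "A"})


def test_fragment_validates_coordinates():
    with pytest.raises(ValueError):
        Fragment(pair=("a", "b"), start=5, end=4, score=1.0, ka_p=0.5)
    f = frag(("a", "b"), start=3, end=7)
    assert f.length == 5


# -- r/m and events ---------------------------------------------------------

def test_rm_counts_qualification_rules():
    track = PosteriorTrack(S=np.array([1.0, 1.0, 1.0, 0.5]),
                           R=np.array([0.99, 0.0, 0.5, 0.0]))
    out = rm_counts(track)
    # site 1: R*S = 0.99 -> recombination; site 2: (1-R)*S = 1 -> mutation
    assert out.n_rec == 1 and out.n_mut == 1


def test_rm_ratio_arithmetic_and_undefined_flag():
    s = np.ones(6)
    r = np.array([0.0, 0.0, 0.96, 0.96, 0.96, 0.96])
    out = rm_counts(PosteriorTrack(S=s, R=r))
    assert (out.n_mut, out.n_rec) == (2, 4)
    assert out.r_over_m == pytest.approx(2.0)
    und = rm_counts(PosteriorTrack(S=np.zeros(3), R=np.zeros(3)))
    assert np.isnan(und.r_over_m) and "undefined_r_over_m" in und.flags


def test_count_events_run_rules():
    r = np.array([0.2, 0.6, 0.96, 0.7, 0.3, 0.55, 0.8, 0.4])
    track = PosteriorTrack(S=np.ones_like(r), R=r)
    assert count_events(track) == 1     # second run peaks below 0.95
    zero = PosteriorTrack(S=np.ones(5), R=np.zeros(5))
    assert count_events(zero) == 0
    r2 = np.array([0.96, 0.96, 0.4, 0.96, 0.96])
    assert count_events(PosteriorTrack(S=np.ones_like(r2), R=r2)) == 2


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                min_size=1, max_size=30))
def test_rm_and_events_match_brute_force_scan(pairs):
    s = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    track = PosteriorTrack(S=s, R=r)
    out = rm_counts(track)
    assert out.n_mut == sum((1 - rv) * sv >= 0.95 for sv, rv in pairs)
    assert out.n_rec == sum(rv * sv >= 0.95 for sv, rv in pairs)
    # brute-force event scan
    events = 0
    in_run = peak = False
    for rv in r:
        if rv >= 0.5:
            if not in_run:
                in_run, peak = True, False
            peak = peak or rv >= 0.95
        else:
            if in_run and peak:
                events += 1
            in_run = False
    if in_run and peak:
        events += 1
    assert count_events(track) == events


def test_track_validates_probabilities():
    with pytest.raises(ValueError):
        PosteriorTrack(S=np.array([1.5]), R=np.array([0.5]))
    with pytest.raises(ValueError):
        PosteriorTrack(S=np.array([0.5, 0.5]), R=np.array([0.5]))
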