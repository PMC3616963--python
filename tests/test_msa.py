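"""Alignment: pairwise DP oracle, progressive MSA, back-translation,
gap-column pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohesim import msa
from cohesim.msa import (CodonAlignment, ProteinAlignment, backtranslate,
                         pairwise_align, progressive_msa, prune_gap_columns)

AA = "ARNDCQEGHILKMFPSTWYV"


def brute_force_affine_score(a, b, S, gap_open, gap_extend):
    """Independent Gotoh DP (score only), first gap char costs gap_open."""
    n, m = len(a), len(b)
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[a[i - 1]][b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


@pytest.fixture(scope="module")
def blosum():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def test_identical_sequences_align_perfectly():
    ra, rb, score, pct, frac = pairwise_align("MKVLAG", "MKVLAG")
    assert ra == rb == "MKVLAG"
    assert pct == 100.0
    assert frac == 1.0


def test_classic_pair_matches_dp_oracle(blosum):
    a, b = "HEAGAWGHEE", "PAWHEAE"
    _, _, score, _, _ = pairwise_align(a, b, gap_open=-8, gap_extend=-1)
    expected = brute_force_affine_score(a, b, blosum, -8, -1)
    assert score == pytest.approx(expected)


def test_single_residue_pair():
    ra, rb, score, pct, frac = pairwise_align("A", "A")
    assert (ra, rb) == ("A", "A")
    assert frac == 1.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        pairwise_align("", "MK")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.text(AA, min_size=1, max_size=12),
       st.text(AA, min_size=1, max_size=12))
def test_pairwise_score_equals_dp_oracle_short_peptides(a, b):
    from Bio.Align import substitution_matrices

    S = substitution_matrices.load("BLOSUM62")
    _, _, score, _, _ = pairwise_align(a, b, gap_open=-11, gap_extend=-1)
    assert score == pytest.approx(
        brute_force_affine_score(a, b, S, -11, -1))


# -- progressive MSA --------------------------------------------------------

def test_identical_sequences_align_without_gaps():
    aln = progressive_msa([("s1", "MKVLAG"), ("s2", "MKVLAG"),
                           ("s3", "MKVLAG")])
    assert all(s == "MKVLAG" for s in aln.seqs)


def test_single_sequence_returned_unchanged():
    aln = progressive_msa([("only", "MKVL")])
    assert aln.names == ["only"] and aln.seqs == ["MKVL"]


def test_unique_insertion_creates_one_gap_block():
    base = "MKVLAGHEWR"
    ins = "MKVLAGQQHEWR"   # unique 2-aa insertion after position 6
    aln = progressive_msa([("a", base), ("b", base), ("c", ins)])
    assert aln.n_columns == len(ins)
    rows = dict(zip(aln.names, aln.seqs))
    assert rows["c"] == ins
    for name in ("a", "b"):
        row = rows[name]
        assert row.count("-") == 2
        gap_start = row.index("-")
        assert row[gap_start: gap_start + 2] == "--"
        assert row.replace("-", "") == base


def test_column_count_at_least_longest_input():
    seqs = [("a", "MKVLAG"), ("b", "MKVL"), ("c", "MKVLAGHE")]
    aln = progressive_msa(seqs)
    assert aln.n_columns >= 8


def test_msa_invariant_to_input_order():
    seqs = [("a", "MKVLAGHEWR"), ("b", "MKVLGHEWR"), ("c", "MKVLAGHEW"),
            ("d", "MKVAGHEWR")]
    a1 = progressive_msa(seqs)
    a2 = progressive_msa(list(reversed(seqs)))
    assert a1.names == a2.names
    assert a1.seqs == a2.seqs


# -- back-translation -------------------------------------------------------

def test_backtranslate_maps_codons_and_gaps():
    p = ProteinAlignment(["x"], ["M-A"])
    out = backtranslate(p, {"x": "ATGGCT"})
    assert out.seqs == ["ATG---GCT"]


def test_backtranslate_tolerates_terminal_stop():
    p = ProteinAlignment(["x"], ["MA"])
    out = backtranslate(p, {"x": "ATGGCTTAA"})
    assert out.seqs == ["ATGGCT"]


def test_backtranslate_rejects_length_mismatch_naming_member():
    p = ProteinAlignment(["gX"], ["MA"])
    with pytest.raises(ValueError, match="gX"):
        backtranslate(p, {"gX": "ATGGC"})


def test_backtranslate_rejects_internal_stop():
    p = ProteinAlignment(["x"], ["M*A"])
    with pytest.raises(ValueError):
        backtranslate(p, {"x": "ATGTAAGCT"})


# -- pruning ----------------------------------------------------------------

def test_prune_is_inclusive_at_threshold():
    rows = ["A-", "A-", "A-", "AC", "AC", "AC"]
    aln = ProteinAlignment([f"s{i}" for i in range(6)], rows)
    out = prune_gap_columns(aln, threshold=0.5)
    # column 2 has 3/6 = 50% gaps: removed (inclusive)
    assert out.seqs == ["A"] * 6


def test_prune_keeps_column_below_threshold():
    rows = ["A-", "A-", "AC", "AC", "AC", "AC"]
    aln = ProteinAlignment([f"s{i}" for i in range(6)], rows)
    out = prune_gap_columns(aln, threshold=0.5)
    assert out.n_columns == 2


def test_prune_gap_free_identity_and_idempotence():
    rows = ["ACD", "ACD", "ACD"]
    aln = ProteinAlignment(["a", "b", "c"], rows)
    once = prune_gap_columns(aln)
    assert once.seqs == rows
    rows2 = ["A--C", "AG-C", "AGGC", "A--C"]
    aln2 = ProteinAlignment(list("abcd"), rows2)
    once2 = prune_gap_columns(aln2)
    twice2 = prune_gap_columns(once2)
    assert once2.seqs == twice2.seqs


def test_codon_pruning_commutes_with_protein_pruning():
    prot = ProteinAlignment(list("abcd"), ["M-A", "MKA", "M-A", "M-A"])
    cds = {"a": "ATGGCT", "b": "ATGAAAGCT", "c": "ATGGCA", "d": "ATGGCC"}
    codon = backtranslate(prot, cds)
    pruned_protein = prune_gap_columns(prot, 0.5)
    pruned_codon = prune_gap_columns(codon, 0.5)
    # codon-column pruning equals protein-column pruning mapped x3
    assert pruned_codon.n_columns == 3 * pruned_protein.n_columns
    kept_protein_cols = [0, 2]
    for row_p, row_c in zip(pruned_protein.seqs, pruned_codon.seqs):
        assert len(row_c) == 3 * len(row_p)
    assert pruned_codon.seqs == ["ATGGCT", "ATGGCT", "ATGGCA", "ATGGCC"]
    assert prot.seqs[1][1] == "K" and 1 not in kept_protein_cols


def test_codon_alignment_validates_frame_and_gap_units():
    with pytest.raises(ValueError):
        CodonAlignment(["x"], ["ATGG"])
    with pytest.raises(ValueError):
        CodonAlignment(["x"], ["AT-GCT"])
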