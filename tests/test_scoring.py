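"""The four column scores, their matrices, and a brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alignscan import (build_frequency_table, builtin_matrix, call_consensus,
                       make_alignment, score_dnaw, score_entropy,
                       score_variability, score_weighted, select_reference,
                       slice_ends)
from alignscan.profile import SliceBounds
from alignscan.scoring import ScoringError, UnknownSymbolError

from conftest import random_alignment


def _profile(records, alphabet=None, master_id=None):
    a = make_alignment(records, alphabet=alphabet)
    ft = build_frequency_table(a, SliceBounds(0, a.length))
    ref = select_reference(a, ft, master_id=master_id)
    return a, ft, ref


# --- matrices --------------------------------------------------------------

def test_identity_dna_matrix_entries():
    m = builtin_matrix("IDENTITY_DNA")
    assert m.get("A", "A") == 5
    assert m.get("A", "C") == -4
    assert m.gap_weight == -4
    assert m.get("A", "-") == -4


def test_simple_dna_ambiguity_scores_mean_of_expansion():
    m = builtin_matrix("SIMPLE_DNA")
    # R = {A, G}: mean of match and mismatch against A
    assert m.get("A", "R") == pytest.approx((5 - 4) / 2)
    assert m.get("R", "A") == pytest.approx(0.5)
    assert m.get("A", "N") == pytest.approx((5 - 4 * 3) / 4)


def test_blosum62_standard_entries():
    m = builtin_matrix("BLOSUM62")
    assert m.get("W", "W") == 11
    assert m.get("L", "I") == 2
    assert m.gap_weight == -4   # minimum off-diagonal entry


def test_unknown_matrix_name_fails():
    with pytest.raises(ScoringError):
        builtin_matrix("PAM250")


# --- hand-evaluated examples ----------------------------------------------

def test_weighted_identity_hand_value():
    # column {A:3, C:1}, consensus A: (3*5 + 1*(-4)) / 4 = 2.75
    _, ft, ref = _profile([("a", "A"), ("b", "A"), ("c", "A"), ("d", "C")])
    s = score_weighted(ft, ref, builtin_matrix("IDENTITY_DNA"))
    assert s.values[0] == pytest.approx(2.75)


def test_weighted_uniform_column_scores_match_weight():
    _, ft, ref = _profile([("a", "G"), ("b", "G"), ("c", "G")])
    s = score_weighted(ft, ref, builtin_matrix("IDENTITY_DNA"))
    assert s.values[0] == pytest.approx(5.0)


def test_weighted_blosum62_hand_value():
    # {L:2, I:2}, consensus I... force L reference via master
    _, ft, ref = _profile(
        [("a", "L"), ("b", "L"), ("c", "I"), ("d", "I")],
        alphabet="PROTEIN", master_id="a")
    s = score_weighted(ft, ref, builtin_matrix("BLOSUM62"))
    assert s.values[0] == pytest.approx((2 * 4 + 2 * 2) / 4)


def test_weighted_unknown_symbol_named_in_error():
    _, ft, ref = _profile([("a", "R"), ("b", "R"), ("c", "A")])
    with pytest.raises(UnknownSymbolError, match="R"):
        score_weighted(ft, ref, builtin_matrix("IDENTITY_DNA"))


def test_dnaw_hand_values(dna4):
    ft = build_frequency_table(dna4, slice_ends(dna4))
    ref = call_consensus(ft)
    s = score_dnaw(ft, ref)
    assert s.values[0] == pytest.approx(1.0)        # uniform column
    assert s.values[5] == pytest.approx(0.5)        # 2/2 split, tie-break A


def test_dnaw_master_mode_no_match_is_zero():
    _, ft, ref = _profile(
        [("a", "A"), ("b", "C"), ("c", "C"), ("d", "C")], master_id="a")
    # master is sole carrier of A -> gamma(A)=1, 1/4; flip: no other matches
    assert score_dnaw(ft, ref).values[0] == pytest.approx(0.25)


def test_dnaw_rejects_protein(protein3):
    ft = build_frequency_table(protein3, slice_ends(protein3))
    with pytest.raises(ScoringError, match="DNA"):
        score_dnaw(ft, call_consensus(ft))


def test_entropy_hand_values():
    _, ft, _ = _profile([("a", "AAA"), ("b", "ACC"), ("c", "ACG"),
                         ("d", "ACT")])
    s = score_entropy(ft)
    assert s.values[0] == 0.0                                   # uniform
    assert s.values[1] == pytest.approx(
        0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))        # -0.8113
    assert s.values[2] == pytest.approx(-2.0)                   # 4-way even


def test_variability_is_one_minus_distinct():
    _, ft, _ = _profile([("a", "AAAA"), ("b", "AACC"), ("c", "ACGG"),
                         ("d", "ACGT")])
    s = score_variability(ft)
    assert list(s.values) == [0.0, -1.0, -2.0, -3.0]


# --- properties ------------------------------------------------------------

def brute_force_scores(a, ref, matrix):
    """Per-column scores by direct loops over sequences (no freq table)."""
    weighted, dnaw, entropy, variability = [], [], [], []
    for i in range(a.length):
        col = a.column(i)
        c = ref[i]
        weighted.append(
            sum(matrix.get(c, ch) for ch in col) / len(col))
        dnaw.append(sum(ch == c for ch in col) / len(col))
        h = 0.0
        for sym in set(col):
            f = col.count(sym) / len(col)
            h -= f * math.log2(f)
        entropy.append(-h)
        variability.append(1 - len(set(col)))
    return weighted, dnaw, entropy, variability


@pytest.mark.parametrize("seed,nseq,length", [(1, 4, 50), (2, 12, 120),
                                              (3, 20, 200)])
def test_all_scores_match_brute_force_oracle(seed, nseq, length):
    rng = np.random.default_rng(seed)
    a = random_alignment(rng, nseq=nseq, length=length, gap_rate=0.03)
    ft = build_frequency_table(a, SliceBounds(0, a.length))
    ref = call_consensus(ft)
    m = builtin_matrix("IDENTITY_DNA")
    w, d, e, v = brute_force_scores(a, ref, m)
    assert np.allclose(score_weighted(ft, ref, m).values, w)
    assert np.allclose(score_dnaw(ft, ref).values, d)
    assert np.allclose(score_entropy(ft).values, e)
    assert np.allclose(score_variability(ft).values, v)


def test_scores_invariant_under_sequence_permutation():
    rng = np.random.default_rng(5)
    a = random_alignment(rng, nseq=7, length=60)
    perm = list(a.records)
    rng.shuffle(perm)
    b = make_alignment(perm, alphabet="DNA")
    m = builtin_matrix("IDENTITY_DNA")
    fa = build_frequency_table(a, SliceBounds(0, a.length))
    fb = build_frequency_table(b, SliceBounds(0, b.length))
    ra, rb = call_consensus(fa), call_consensus(fb)
    assert np.allclose(score_weighted(fa, ra, m).values,
                       score_weighted(fb, rb, m).values)
    assert np.allclose(score_entropy(fa).values, score_entropy(fb).values)
    assert np.allclose(score_dnaw(fa, ra).values, score_dnaw(fb, rb).values)
    assert np.allclose(score_variability(fa).values,
                       score_variability(fb).values)


@given(st.lists(st.sampled_from("ACGT-"), min_size=2, max_size=20))
@settings(max_examples=60, deadline=None)
def test_entropy_nonpositive_zero_iff_uniform(column):
    if all(ch == "-" for ch in column):
        return
    records = [(f"s{i}", ch + "AC") for i, ch in enumerate(column)]
    a = make_alignment(records, alphabet="DNA")
    ft = build_frequency_table(a, SliceBounds(0, 3))
    s = score_entropy(ft).values[0]
    assert s <= 0.0
    assert (s == 0.0) == (len(set(column)) == 1)


@given(st.lists(st.sampled_from("ACGT"), min_size=2, max_size=16))
@settings(max_examples=60, deadline=None)
def test_dnaw_bounded_and_one_iff_all_match(column):
    records = [(f"s{i}", ch) for i, ch in enumerate(column)]
    a = make_alignment(records, alphabet="DNA")
    ft = build_frequency_table(a, SliceBounds(0, 1))
    ref = call_consensus(ft)
    s = score_dnaw(ft, ref).values[0]
    assert 0.0 <= s <= 1.0
    assert (s == 1.0) == (len(set(column)) == 1)


def test_weighted_identity_increases_with_consensus_matches():
    # for fixed nseq, more consensus matches -> strictly higher score
    m = builtin_matrix("IDENTITY_DNA")
    scores = []
    nseq = 8
    for k in range(1, nseq + 1):
        col = "A" * k + "C" * (nseq - k)
        records = [(f"s{i}", ch) for i, ch in enumerate(col)]
        a = make_alignment(records, alphabet="DNA")
        ft = build_frequency_table(a, SliceBounds(0, 1))
        ref = select_reference(a, ft, master_id="s0")   # reference A
        scores.append(score_weighted(ft, ref, m).values[0])
    assert all(b > a for a, b in zip(scores, scores[1:]))
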