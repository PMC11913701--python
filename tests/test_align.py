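import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_optimum, score_gapped_pair
from orthoquery.align import (GAP, MultipleAlignment, ScoringScheme, ScoringError,
                              global_align, pairwise_identity,
                              percent_identity_matrix, progressive_msa)

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_st = st.text(alphabet=AA, min_size=1, max_size=5)


def test_blosum62_identity_score(scheme):
    # three A/A matches under the published matrix, no gaps
    ga, gb, score = global_align("AAA", "AAA", scheme)
    assert (ga, gb) == ("AAA", "AAA")
    assert score == 3 * scheme.score_pair("A", "A") == 12


def test_self_alignment_has_no_gaps(scheme):
    seq = "MKVWLAACDEFGHIK"
    ga, gb, score = global_align(seq, seq, scheme)
    assert ga == gb == seq
    assert score == scheme.self_score(seq)


@settings(derandomize=True, max_examples=80)
@given(seq_st, seq_st)
def test_score_matches_exhaustive_enumeration(scheme, a, b):
    _, _, score = global_align(a, b, scheme)
    assert score == pytest.approx(brute_force_optimum(a, b, scheme), abs=1e-9)


@settings(derandomize=True, max_examples=40)
@given(seq_st, seq_st)
def test_reported_alignment_scores_its_own_score(scheme, a, b):
    ga, gb, score = global_align(a, b, scheme)
    assert ga.replace(GAP, "") == a and gb.replace(GAP, "") == b
    assert score_gapped_pair(ga, gb, scheme) == pytest.approx(score, abs=1e-9)


def test_score_agrees_with_biopython_on_longer_pairs(scheme):
    rng = np.random.default_rng(42)
    b62 = substitution_matrices.load("BLOSUM62")
    aligner = PairwiseAligner(substitution_matrix=b62, mode="global",
                              open_gap_score=-scheme.gap_open,
                              extend_gap_score=-scheme.gap_extend)
    for _ in range(25):
        a = "".join(rng.choice(list(AA), size=rng.integers(5, 60)))
        b = "".join(rng.choice(list(AA), size=rng.integers(5, 60)))
        assert global_align(a, b, scheme)[2] == pytest.approx(aligner.score(a, b))


def test_score_is_symmetric(scheme):
    rng = np.random.default_rng(7)
    for _ in range(10):
        a = "".join(rng.choice(list(AA), size=rng.integers(3, 30)))
        b = "".join(rng.choice(list(AA), size=rng.integers(3, 30)))
        assert global_align(a, b, scheme)[2] == pytest.approx(global_align(b, a, scheme)[2])


def test_optimality_beats_hand_alignment(scheme):
    # the optimum cannot be worse than any specific alignment we write down
    a, b = "MKVLW", "MKLW"
    hand = ("MKVLW", "MK-LW")
    _, _, score = global_align(a, b, scheme)
    assert score >= score_gapped_pair(*hand, scheme)


def test_unknown_residue_named_in_error(scheme):
    with pytest.raises(ScoringError, match="'1'"):
        global_align("MK1", "MKV", scheme)


def test_empty_sequence_rejected(scheme):
    with pytest.raises(ValueError):
        global_align("", "MKV", scheme)


def test_gap_extend_cannot_exceed_open():
    with pytest.raises(ValueError):
        ScoringScheme.blosum62(gap_open=1, gap_extend=2)


def test_msa_identical_sequences_have_no_gaps(scheme):
    msa = progressive_msa([("a", "MKVW"), ("b", "MKVW"), ("c", "MKVW")], scheme)
    assert msa.rows == ["MKVW"] * 3


def test_msa_single_insertion(scheme):
    msa = progressive_msa([("a", "MKV"), ("b", "MKKV")], scheme)
    assert msa.n_columns == 4
    assert msa.rows[0].count(GAP) == 1 and msa.rows[1].count(GAP) == 0


def test_msa_degapping_recovers_inputs(scheme):
    seqs = [("a", "MKVLLAW"), ("b", "MKGWLAW"), ("c", "MKVLAW"), ("d", "MKVLLAWYY")]
    msa = progressive_msa(seqs, scheme)
    assert msa.labels == [s[0] for s in seqs]
    for i, (_, seq) in enumerate(seqs):
        assert msa.degapped(i) == seq


def test_msa_single_record_warns(scheme):
    with pytest.warns(UserWarning):
        msa = progressive_msa([("a", "MKV")], scheme)
    assert msa.rows == ["MKV"]


def test_alignment_invariants_enforced():
    with pytest.raises(ValueError, match="equal length"):
        MultipleAlignment(["a", "b"], ["MKV", "MKVW"])
    with pytest.raises(ValueError, match="all-gap"):
        MultipleAlignment(["a", "b"], ["M-V", "M-W"])


def test_pim_trivial_values():
    msa = MultipleAlignment(["a", "b"], ["AAAA", "TTTT"])
    pim = percent_identity_matrix(msa)
    assert pim.values[0, 0] == pim.values[1, 1] == 100.0
    assert pim.values[0, 1] == 0.0


def test_pim_gap_columns_excluded_from_denominator():
    # 3 co-residue columns, all identical -> 100 despite the gap
    msa = MultipleAlignment(["a", "b"], ["MK-V", "MKAV"])
    pim = percent_identity_matrix(msa)
    assert pim.values[0, 1] == 100.0


def test_pim_denominator_modes():
    msa = MultipleAlignment(["a", "b"], ["MK-V", "MKAV"])
    assert percent_identity_matrix(msa, "co_residue").values[0, 1] == 100.0
    assert percent_identity_matrix(msa, "shorter").values[0, 1] == 100.0
    assert percent_identity_matrix(msa, "alignment").values[0, 1] == 75.0
    with pytest.raises(ValueError):
        percent_identity_matrix(msa, "bogus")


def test_pim_permutation_equivariance(scheme):
    seqs = [("a", "MKVLLAW"), ("b", "MKGWLAW"), ("c", "MKVLAW")]
    msa = progressive_msa(seqs, scheme)
    pim = percent_identity_matrix(msa)
    perm = [2, 0, 1]
    permuted = MultipleAlignment([msa.labels[i] for i in perm],
                                 [msa.rows[i] for i in perm])
    pim_p = percent_identity_matrix(permuted)
    assert np.allclose(pim_p.values, pim.values[np.ix_(perm, perm)])


def test_pairwise_identity_single_substitution(scheme):
    a = "MKVW" * 25  # 100 residues
    b = "A" + a[1:]
    assert pairwise_identity(a, b, scheme) == pytest.approx(99.0)
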