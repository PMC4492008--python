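"""Profile-HMM construction, Forward/Viterbi scoring, and the enumeration
oracle.  The oracle (tests/conftest.py) sums over explicitly enumerated state
paths, fully independent of the dynamic-programming implementation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import enumerate_paths, random_query, random_small_profile
from hmmstitch import (
    DNA,
    Alignment,
    SequenceRecord,
    build_profile,
    forward_bitscore,
    viterbi_align,
)
from hmmstitch.errors import SequenceFormatError


class TestBuildProfile:
    def test_match_state_per_occupied_column(self):
        hmm = build_profile(Alignment({"a": "A-C", "b": "AGC"}, DNA))
        assert hmm.K == 3
        assert hmm.column_map.tolist() == [0, 1, 2]

    def test_all_gap_columns_dropped_from_column_map(self):
        hmm = build_profile(Alignment({"a": "A-", "b": "C-"}, DNA))
        assert hmm.K == 1
        assert hmm.column_map.tolist() == [0]

    def test_laplace_emission_estimate(self):
        # two A residues over a 4-letter alphabet, alpha=1: (2+1)/(2+4)
        hmm = build_profile(Alignment({"a": "A", "b": "A"}, DNA), pseudocount=1.0)
        a_idx = DNA.index("A")
        assert hmm.match_emissions[0, a_idx] == pytest.approx(0.5)
        for other in "CGT":
            assert hmm.match_emissions[0, DNA.index(other)] == pytest.approx(1 / 6)

    def test_probability_bundles_normalised(self):
        hmm = build_profile(
            Alignment({"a": "ACGT", "b": "A-GT", "c": "AC-T"}, DNA)
        )
        hmm.validate()  # raises on any unnormalised bundle

    def test_row_order_invariance(self):
        rows = {"a": "AC-T", "b": "-CGT", "c": "ACG-"}
        h1 = build_profile(Alignment(rows, DNA))
        h2 = build_profile(Alignment(dict(reversed(rows.items())), DNA))
        q = SequenceRecord("q", "ACGT", DNA)
        assert forward_bitscore(h1, q) == pytest.approx(
            forward_bitscore(h2, q), abs=1e-12
        )

    def test_empty_alignment_rejected(self):
        with pytest.raises(Exception):
            build_profile(Alignment({"a": "--", "b": "--"}, DNA))


class TestForward:
    def test_null_emissions_make_residues_indistinguishable(self):
        # match emission == null: only transition terms remain in the score
        hmm = build_profile(Alignment({"a": "A", "b": "C", "c": "G", "d": "T"}, DNA))
        assert np.allclose(hmm.match_emissions[0], hmm.null_frequencies)
        s1 = forward_bitscore(hmm, SequenceRecord("q", "A", DNA))
        s2 = forward_bitscore(hmm, SequenceRecord("q", "C", DNA))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_matches_enumeration_oracle_on_training_sequence(self):
        hmm = build_profile(Alignment({"a": "AC", "b": "AC"}, DNA))
        q = SequenceRecord("q", "AC", DNA)
        fwd_oracle, _ = enumerate_paths(hmm, q)
        assert forward_bitscore(hmm, q) == pytest.approx(fwd_oracle, abs=1e-9)

    def test_matches_oracle_on_fragment(self):
        hmm = build_profile(Alignment({"a": "AC", "b": "AC"}, DNA))
        q = SequenceRecord("q", "A", DNA)
        fwd_oracle, _ = enumerate_paths(hmm, q)
        assert forward_bitscore(hmm, q) == pytest.approx(fwd_oracle, abs=1e-9)

    def test_ambiguity_codes_score_at_null(self):
        hmm = build_profile(Alignment({"a": "ACGT", "b": "ACGT"}, DNA))
        # all-N query: every emission contributes log-odds 0
        sN = forward_bitscore(hmm, SequenceRecord("q", "NNNN", DNA))
        f, _ = enumerate_paths(hmm, SequenceRecord("q", "NNNN", DNA))
        assert sN == pytest.approx(f, abs=1e-9)

    def test_alphabet_mismatch_rejected(self):
        from hmmstitch import AMINO

        hmm = build_profile(Alignment({"a": "ACGT"}, DNA))
        with pytest.raises(SequenceFormatError, match="alphabet"):
            forward_bitscore(hmm, SequenceRecord("q", "MKL", AMINO))

    def test_long_query_does_not_underflow(self):
        rng = np.random.default_rng(5)
        rows = {f"r{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(3)}
        hmm = build_profile(Alignment(rows, DNA))
        q = SequenceRecord("q", "".join(rng.choice(list("ACGT"), 10_000)), DNA)
        assert np.isfinite(forward_bitscore(hmm, q))


class TestViterbi:
    def test_training_sequence_maps_onto_all_match_states(self):
        hmm = build_profile(Alignment({"a": "ACGT", "b": "ACGT"}, DNA))
        path = viterbi_align(hmm, SequenceRecord("q", "ACGT", DNA))
        assert path.steps == [("M", 1), ("M", 2), ("M", 3), ("M", 4)]

    def test_extra_residue_path_is_the_enumerated_argmax(self):
        # with only two training rows the insert penalty (~log2 n + log2 3
        # bits) exceeds the match gain of the suffix, so the best local path
        # exits early; the enumeration oracle is the authority either way
        hmm = build_profile(Alignment({"a": "ACGT", "b": "ACGT"}, DNA))
        q = SequenceRecord("q", "ACNGT", DNA)
        path = viterbi_align(hmm, q)
        _, vit_oracle = enumerate_paths(hmm, q)
        assert path.score == pytest.approx(vit_oracle, abs=1e-9)
        assert path.emitted_count() == 5

    def test_mid_query_insertion_wins_with_strong_training_signal(self):
        # ten identical training rows make match states informative enough to
        # pay the insert penalty: the extra N lands in the insert slot after
        # match state 4 and both flanks stay aligned
        rows = {f"r{i}": "ACGTACGT" for i in range(10)}
        hmm = build_profile(Alignment(rows, DNA))
        q = SequenceRecord("q", "ACGTNACGT", DNA)
        path = viterbi_align(hmm, q)
        assert path.steps == [
            ("M", 1), ("M", 2), ("M", 3), ("M", 4), ("I", 4),
            ("M", 5), ("M", 6), ("M", 7), ("M", 8),
        ]
        _, vit_oracle = enumerate_paths(hmm, q)
        assert path.score == pytest.approx(vit_oracle, abs=1e-9)

    def test_missing_residue_path_is_the_enumerated_argmax(self):
        hmm = build_profile(Alignment({"a": "ACGT", "b": "ACGT"}, DNA))
        q = SequenceRecord("q", "ACT", DNA)
        path = viterbi_align(hmm, q)
        _, vit_oracle = enumerate_paths(hmm, q)
        assert path.score == pytest.approx(vit_oracle, abs=1e-9)
        # every residue covered exactly once
        assert path.emitted_count() == 3

    def test_forward_at_least_viterbi(self, rng):
        for _ in range(25):
            hmm = random_small_profile(rng)
            q = random_query(rng)
            f = forward_bitscore(hmm, q)
            v = viterbi_align(hmm, q).score
            assert f >= v - 1e-9


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_forward_and_viterbi_match_oracle_randomised(seed):
    """Both scores agree with the explicit path enumeration on small models."""
    rng = np.random.default_rng(seed)
    hmm = random_small_profile(rng)
    q = random_query(rng)
    fwd_oracle, vit_oracle = enumerate_paths(hmm, q)
    assert forward_bitscore(hmm, q) == pytest.approx(fwd_oracle, abs=1e-9)
    assert viterbi_align(hmm, q).score == pytest.approx(vit_oracle, abs=1e-9)


def test_serialization_round_trip(tmp_path, rng):
    from hmmstitch.phmm import ProfileHMM

    hmm = random_small_profile(rng)
    path = tmp_path / "model.txt"
    hmm.save(path)
    back = ProfileHMM.load(path)
    np.testing.assert_allclose(back.match_emissions, hmm.match_emissions, atol=1e-15)
    np.testing.assert_allclose(back.transitions, hmm.transitions, atol=1e-15)
    assert back.column_map.tolist() == hmm.column_map.tolist()
    q = random_query(rng)
    assert forward_bitscore(back, q) == pytest.approx(
        forward_bitscore(hmm, q), abs=1e-12
    )
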