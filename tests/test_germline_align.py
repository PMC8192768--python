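"""Alignment, numbering transfer and somatic-mutation encoding."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import lctox as lx
from lctox.germline_align import DEFAULT_SCORING
from lctox.io_formats import MISSING, kabat_key

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_best_score(a, b, match=1, mismatch=-1, gap=-2):
    """Enumerate every global alignment recursively; DP-free oracle."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            s = (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1)
            best = s
        if i < len(a):
            s = gap + rec(i + 1, j)
            best = s if best is None else max(best, s)
        if j < len(b):
            s = gap + rec(i, j + 1)
            best = s if best is None else max(best, s)
        return best

    return rec(0, 0)


class TestGlobalAlign:
    def test_worked_example_gapless(self):
        pair = lx.global_align("SYELTQPP", "SYVLTQPP")
        assert pair.lc_aligned == "SYELTQPP"
        assert pair.gl_aligned == "SYVLTQPP"
        matches = sum(a == b for a, b in zip(pair.lc_aligned, pair.gl_aligned))
        assert (matches, len(pair.lc_aligned) - matches) == (7, 1)
        assert pair.score == 7 * 1 + 1 * (-1)

    def test_identical_sequences(self):
        pair = lx.global_align("QSVLTQ", "QSVLTQ")
        assert pair.score == 6 and "-" not in pair.lc_aligned

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            lx.global_align("", "ACD")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text("ACD", min_size=1, max_size=5),
           st.text("ACD", min_size=1, max_size=5))
    def test_score_matches_enumeration_oracle(self, a, b):
        assert lx.global_align(a, b).score == brute_force_best_score(a, b)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(AA, min_size=1, max_size=12),
           st.text(AA, min_size=1, max_size=12))
    def test_score_matches_biopython(self, a, b):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1, -1
        aligner.open_gap_score = aligner.extend_gap_score = -2
        assert lx.global_align(a, b).score == aligner.score(a, b)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(AA, min_size=1, max_size=8),
           st.text(AA, min_size=1, max_size=8))
    def test_score_symmetric_under_swap(self, a, b):
        assert lx.global_align(a, b).score == lx.global_align(b, a).score

    def test_alignment_recovers_originals(self):
        pair = lx.global_align("QSVLT", "QSVAALT")
        assert pair.lc_aligned.replace("-", "") == "QSVLT"
        assert pair.gl_aligned.replace("-", "") == "QSVAALT"


class TestTransferNumbering:
    def test_gapless_inherits_labels(self, tiny_germline):
        pair = lx.global_align("SYELTQPP", tiny_germline.sequence)
        assert lx.transfer_numbering(pair, tiny_germline) == list(tiny_germline.kc_labels)

    def test_insertion_gets_letter(self):
        gl = lx.GermlineRecord("g", "ACDF", ("29", "30", "31", "32"))
        pair = lx.AlignedPair("ACWDF", "AC-DF", 0.0)
        assert lx.transfer_numbering(pair, gl) == ["29", "30", "30A", "31", "32"]

    def test_insertion_after_existing_letter_continues(self):
        gl = lx.GermlineRecord("g", "ACD", ("30", "30A", "31"))
        pair = lx.AlignedPair("ACWD", "AC-D", 0.0)
        assert lx.transfer_numbering(pair, gl) == ["30", "30A", "30B", "31"]

    def test_deletion_drops_exactly_that_label(self):
        # 6-residue case: LC lacks the germline's 4th residue
        gl = lx.GermlineRecord("g", "ACDEFG", tuple("123456"))
        pair = lx.AlignedPair("ACD-FG", "ACDEFG", 0.0)
        assert lx.transfer_numbering(pair, gl) == ["1", "2", "3", "5", "6"]

    def test_germline_row_must_match(self, tiny_germline):
        pair = lx.AlignedPair("ACD", "ACD", 0.0)
        with pytest.raises(ValueError, match="germline row"):
            lx.transfer_numbering(pair, tiny_germline)


class TestRenumberProgressive:
    def test_cdr1_insertions_shift_numbering(self):
        universe = [str(i) for i in range(1, 31)] + \
            ["30A", "30B", "30C", "30D", "30E", "30F"] + \
            [str(i) for i in range(31, 40)]
        scheme = lx.renumber_progressive(universe)
        assert [scheme[l] for l in ["30", "30A", "30B", "30C", "30D", "30E", "30F", "31"]] \
            == [30, 31, 32, 33, 34, 35, 36, 37]

    def test_no_insertions_is_rank_identity(self):
        universe = [str(i) for i in range(1, 20)]
        assert lx.renumber_progressive(universe) == {str(i): i for i in range(1, 20)}

    def test_duplicate_label_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            lx.renumber_progressive(["1", "2", "2"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.tuples(st.integers(1, 60), st.sampled_from(["", "A", "B"])),
                   min_size=1, max_size=40))
    def test_monotone_dense_bijection(self, keys):
        universe = [f"{n}{ins}" for n, ins in keys]
        scheme = lx.renumber_progressive(universe)
        assert sorted(scheme.values()) == list(range(1, len(universe) + 1))
        ordered = sorted(universe, key=kabat_key)
        assert [scheme[l] for l in ordered] == list(range(1, len(universe) + 1))

    def test_toy_reference_is_contiguous(self, toy_scheme_map):
        assert sorted(toy_scheme_map.values()) == list(range(1, len(toy_scheme_map) + 1))


class TestEncodeSmut:
    def _encode(self, lc_seq, gl):
        scheme = lx.renumber_progressive(list(gl.kc_labels))
        ng = lx.number_germline(gl, scheme)
        nl = lx.number_sequence("lc", lc_seq, gl, scheme)
        return lx.encode_smut(nl, ng), ng

    def test_worked_example(self, tiny_germline):
        enc, _ = self._encode("SYELTQPP", tiny_germline)
        tokens = "".join(enc.token_by_position[p] for p in sorted(enc.token_by_position))
        assert tokens == "XXEXXXXX"
        assert enc.n_sm == 1

    def test_identity_is_all_x(self, tiny_germline):
        enc, _ = self._encode(tiny_germline.sequence, tiny_germline)
        assert set(enc.token_by_position.values()) == {"X"}
        assert enc.n_sm == 0

    def test_truncation_marks_missing(self, tiny_germline):
        enc, _ = self._encode("SYVLT", tiny_germline)
        assert [enc.token_by_position[p] for p in (6, 7, 8)] == [MISSING] * 3

    def test_lc_position_outside_germline_flagged(self):
        lc = lx.NumberedSequence("lc", {1: "A", 2: "C"}, "g")
        gl = lx.NumberedSequence("g", {1: "A"}, "g")
        with pytest.raises(ValueError, match="absent from germline"):
            lx.encode_smut(lc, gl)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_reconstruction_and_hamming(self, toy_germlines, data):
        """Applying tokens onto the germline recovers the LC; n_sm is the
        Hamming distance over covered positions."""
        gl = data.draw(st.sampled_from(sorted(toy_germlines)))
        gl = toy_germlines[gl]
        seq = list(gl.sequence)
        n_mut = data.draw(st.integers(0, 6))
        idx = data.draw(st.permutations(range(len(seq)))) [:n_mut]
        for i in idx:
            seq[i] = data.draw(st.sampled_from([a for a in AA if a != gl.sequence[i]]))
        lc_seq = "".join(seq)
        enc, ng = self._encode(lc_seq, gl)
        assert enc.n_sm == sum(a != b for a, b in zip(lc_seq, gl.sequence))
        decoded = lx.decode_smut(enc, ng)
        assert "".join(decoded[p] for p in sorted(decoded)) == lc_seq
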