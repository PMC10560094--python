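import random

import pytest

from isoimpact.align import (
    MSA,
    AlignParams,
    external_aligner_ingest,
    global_align,
    identity_fraction,
    progressive_msa,
    write_aligned_fasta,
)
from isoimpact.model import AMINO_ACIDS, DomainError, ValidationError


class TestGlobalAlign:
    def test_identical_sequences(self, align_params):
        a, b, score = global_align("AAA", "AAA", align_params)
        assert (a, b) == ("AAA", "AAA")
        assert score == 12  # 3 * BLOSUM62[A, A]

    def test_single_gap_cost(self, align_params):
        a, b, score = global_align("A", "", align_params)
        assert (a, b) == ("A", "-")
        assert score == -(align_params.gap_open + align_params.gap_extend)

    def test_both_empty(self, align_params):
        assert global_align("", "", align_params) == ("", "", 0)

    def test_gap_run_charged_once(self, align_params):
        # one run of 3 vs three runs of 1: -(10 + 3) vs -3 * 11
        _, b, score = global_align("WWWAAA", "AAA", align_params)
        assert b == "---AAA"
        assert score == 12 - 13

    def test_score_symmetric(self, align_params):
        rng = random.Random(5)
        for _ in range(25):
            a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 12)))
            assert global_align(a, b, align_params)[2] == global_align(b, a, align_params)[2]

    def test_degapping_recovers_inputs(self, align_params):
        aa, bb, _ = global_align("MKVLA", "MVLA", align_params)
        assert aa.replace("-", "") == "MKVLA"
        assert bb.replace("-", "") == "MVLA"

    def test_rejects_illegal_residue(self, align_params):
        with pytest.raises(DomainError, match="absent from the substitution matrix"):
            global_align("A-C", "AC", align_params)


class TestAlignParams:
    def test_gap_order_enforced(self):
        with pytest.raises(ValidationError):
            AlignParams(gap_open=1, gap_extend=5)

    def test_unknown_matrix(self):
        with pytest.raises(ValidationError, match="unknown substitution matrix"):
            AlignParams(matrix_name="NOSUCH99")

    def test_x_scores(self, align_params):
        # X is a residue, never an identity bonus: BLOSUM62 X:X = -1
        _, _, score = global_align("X", "X", align_params)
        assert score == -1


class TestIdentityFraction:
    def test_shorter_denominator(self):
        assert identity_fraction("ACD", "ACD", "ACD", "ACD") == 1.0
        assert identity_fraction("ACDE", "ACD-", "ACDE", "ACD") == 1.0

    def test_x_never_identical(self):
        assert identity_fraction("AX", "AX", "AX", "AX") == 0.5


class TestProgressiveMSA:
    def test_single_sequence(self, align_params):
        msa = progressive_msa([("a", "ACDE")], "a", align_params)
        assert msa.rows == ["ACDE"]

    def test_recovers_planted_gap_block(self, align_params):
        canonical = "MKVLITAGPTREPLDSVRAIS"
        deleted = canonical[:8] + canonical[14:]  # drop 6 residues
        msa = progressive_msa(
            [("c", canonical), ("d", deleted), ("e", canonical)], "c", align_params
        )
        assert msa.row("d") == canonical[:8] + "------" + canonical[14:]

    def test_order_invariance(self, align_params):
        seqs = [("a", "MKVLITAGPT"), ("b", "MKVLAGPT"), ("c", "MKVLITAGPA")]
        msa1 = progressive_msa(seqs, "a", align_params)
        msa2 = progressive_msa(list(reversed(seqs)), "a", align_params)
        assert {i: msa1.row(i) for i in "abc"} == {i: msa2.row(i) for i in "abc"}

    def test_degap_preserves_every_input(self, align_params):
        rng = random.Random(11)
        seqs = [
            (f"s{i}", "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(8, 20))))
            for i in range(4)
        ]
        msa = progressive_msa(seqs, "s0", align_params)
        for sid, seq in seqs:
            assert msa.degapped(sid) == seq

    def test_duplicate_ids_rejected(self, align_params):
        with pytest.raises(ValidationError):
            progressive_msa([("a", "ACD"), ("a", "ACD")], "a", align_params)

    def test_unknown_canonical_rejected(self, align_params):
        with pytest.raises(DomainError):
            progressive_msa([("a", "ACD")], "z", align_params)


class TestMSAInvariants:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValidationError):
            MSA(["a", "b"], ["AC-", "AC"], "a")

    def test_all_gap_column_rejected(self):
        with pytest.raises(ValidationError, match="all-gap"):
            MSA(["a", "b"], ["A-C", "A-C"], "a")


class TestExternalIngest:
    def test_roundtrip(self, tmp_path, align_params):
        seqs = [("a", "MKVLITAGPT"), ("b", "MKVLAGPT")]
        msa = progressive_msa(seqs, "a", align_params)
        path = tmp_path / "aln.fasta"
        write_aligned_fasta(msa, path)
        back = external_aligner_ingest(path, seqs, "a")
        assert back.rows == msa.rows

    def test_sequence_mismatch_names_position(self, tmp_path):
        (tmp_path / "aln.fasta").write_text(">a\nMKVA\n>b\nMK-A\n")
        with pytest.raises(ValidationError, match="position 3"):
            external_aligner_ingest(
                tmp_path / "aln.fasta", [("a", "MKLA"), ("b", "MKA")], "a"
            )

    def test_missing_row_rejected(self, tmp_path):
        (tmp_path / "aln.fasta").write_text(">a\nMKVA\n")
        with pytest.raises(ValidationError, match="missing"):
            external_aligner_ingest(tmp_path / "aln.fasta", [("a", "MKVA"), ("b", "MK")], "a")
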