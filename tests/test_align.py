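import shutil

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from pstrtool.align import (
    AlignedPair,
    ExternalAligner,
    GAP_EXTEND,
    GAP_OPEN,
    align_pair,
    all_pairs,
)
from pstrtool.seqio import ProteinRecord

AA = list("ACDEFGHIKLMNPQRSTVWY")


def reference_aligner():
    """Biopython global aligner with the same scoring model."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def rescore(pair: AlignedPair) -> float:
    """Recompute the alignment score from the rows (traceback validity)."""
    blosum = substitution_matrices.load("BLOSUM62")
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(pair.row_a, pair.row_b):
        if ca == "-":
            score -= GAP_OPEN if not in_gap_a else GAP_EXTEND
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= GAP_OPEN if not in_gap_b else GAP_EXTEND
            in_gap_b, in_gap_a = True, False
        else:
            score += blosum[ca, cb]
            in_gap_a = in_gap_b = False
    return score


class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self):
        pair = align_pair(ProteinRecord("a", "MKW"), ProteinRecord("b", "MKW"))
        assert pair.row_a == "MKW" and pair.row_b == "MKW"

    def test_repeat_gap_is_placed_c_terminally(self):
        pair = align_pair(
            ProteinRecord("a", "MKPQPQW"), ProteinRecord("b", "MKPQW")
        )
        assert (pair.row_a, pair.row_b) == ("MKPQPQW", "MKPQ--W")
        # hand value: matches M5+K5+P7+Q5+W11 = 33, one gap of 2: -10-0.5
        assert pair.score == pytest.approx(22.5)

    def test_input_order_symmetry(self):
        a, b = ProteinRecord("a", "MKPQPQW"), ProteinRecord("b", "MKPQW")
        ab, ba = align_pair(a, b), align_pair(b, a)
        assert (ab.row_a, ab.row_b) == (ba.row_b, ba.row_a)

    def test_x_sequences_rejected(self):
        with pytest.raises(ValueError, match="X"):
            align_pair(ProteinRecord("a", "MXK"), ProteinRecord("b", "MKK"))

    def test_gap_strip_round_trip_and_column_maps(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            sa = "".join(rng.choice(AA, size=int(rng.integers(1, 30))))
            sb = "".join(rng.choice(AA, size=int(rng.integers(1, 30))))
            pair = align_pair(ProteinRecord("a", sa), ProteinRecord("b", sb))
            assert pair.seq_a == sa and pair.seq_b == sb
            col_a = pair.col_to_pos("a")
            assert [p for p in col_a if p] == list(range(1, len(sa) + 1))
            pos_a = pair.pos_to_col("a")
            for pos in range(1, len(sa) + 1):
                assert col_a[pos_a[pos]] == pos

    def test_score_matches_reference_dynamic_program(self):
        aligner = reference_aligner()
        rng = np.random.default_rng(5)
        for _ in range(60):
            sa = "".join(rng.choice(AA, size=int(rng.integers(1, 21))))
            sb = "".join(rng.choice(AA, size=int(rng.integers(1, 21))))
            pair = align_pair(ProteinRecord("a", sa), ProteinRecord("b", sb))
            assert pair.score == pytest.approx(aligner.score(sa, sb))
            assert rescore(pair) == pytest.approx(pair.score)


class TestAlignedPair:
    def test_row_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            AlignedPair("a", "b", "MK-", "MK")

    def test_double_gap_column_rejected(self):
        with pytest.raises(ValueError, match="both"):
            AlignedPair("a", "b", "M-K", "M-K")


class TestAllPairs:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (10, 45)])
    def test_pair_count(self, n, expected):
        rng = np.random.default_rng(n)
        records = [
            ProteinRecord(f"s{i}", "".join(rng.choice(AA, size=12)))
            for i in range(n)
        ]
        pairs = list(all_pairs(records))
        assert len(pairs) == expected
        assert [(i, j) for i, j, _ in pairs] == [
            (i, j) for i in range(n) for j in range(i + 1, n)
        ]

    def test_single_record_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            list(all_pairs([ProteinRecord("a", "MK")]))

    def test_identical_records_align_gap_free(self):
        records = [ProteinRecord("a", "MKLVW"), ProteinRecord("b", "MKLVW")]
        (_, _, pair), = all_pairs(records)
        assert "-" not in pair.row_a + pair.row_b


class TestExternalBackend:
    def test_mafft_adapter_round_trips(self):
        mafft = shutil.which("mafft")
        assert mafft, "mafft expected on PATH in the test environment"
        backend = ExternalAligner(mafft, "{exe} --quiet {input}")
        a = ProteinRecord("a", "MKVCWDEPQPQPQHLSTRNAEY")
        b = ProteinRecord("b", "MKVCWDEPQPQHLSTRNAEY")
        pair = align_pair(a, b, backend=backend)
        assert pair.seq_a == a.sequence and pair.seq_b == b.sequence
        assert pair.row_a.count("-") + pair.row_b.count("-") >= 2

    def test_missing_executable_raises_with_stderr(self):
        backend = ExternalAligner("definitely-not-an-aligner")
        with pytest.raises((RuntimeError, OSError)):
            align_pair(
                ProteinRecord("a", "MKV"), ProteinRecord("b", "MKV"),
                backend=backend,
            )

    def test_unknown_backend_name_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            align_pair(
                ProteinRecord("a", "MKV"), ProteinRecord("b", "MKV"),
                backend="nonsense",
            )
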