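import pytest

from sisterrates.alignments import (
    Alignment,
    AlignmentError,
    Partition,
    concatenate,
    flag_pseudogenes,
    mask_columns,
    read_alignment,
)


@pytest.fixture
def coding_aln():
    return Alignment(
        {"s1": "ATGGCTGCTAAA", "s2": "ATGGCAGCCAAA", "s3": "atggctgcgaag"},
        partitions=[Partition("g1", 0, 12, coding=True)],
    )


def test_read_fasta_with_coding_partition(tmp_path, coding_aln):
    p = tmp_path / "a.fasta"
    coding_aln.write_fasta(p)
    aln = read_alignment(p, partitions=[("g1", 1, 12, True)])
    assert aln.n_columns == 12
    assert aln.partitions[0].length == 12
    assert aln.records["s3"] == "ATGGCTGCGAAG"  # lowercase normalized


def test_ragged_fasta_rejected(tmp_path):
    (tmp_path / "r.fasta").write_text(">a\nACGT\n>b\nACG\n")
    with pytest.raises(AlignmentError, match="unequal sequence lengths"):
        read_alignment(tmp_path / "r.fasta")


def test_partition_out_of_bounds():
    with pytest.raises(AlignmentError, match="out of bounds"):
        Alignment(
            {"a": "ACGTACGTACGT"},
            partitions=[Partition("g", 9, 15)],
        )


def test_coding_partition_must_be_codon_sized():
    with pytest.raises(AlignmentError, match="divisible by 3"):
        Alignment({"a": "ACGTA"}, partitions=[Partition("g", 0, 5, coding=True)])


class TestMaskColumns:
    def test_mask_removes_columns_and_reindexes(self):
        aln = Alignment({"a": "ACGTACGTACGT"}, partitions=[Partition("g", 0, 12)])
        out = mask_columns(aln, [(4, 6)])
        assert out.n_columns == 9
        assert out.records["a"] == "ACGGTACGT"
        assert (out.partitions[0].start, out.partitions[0].end) == (0, 9)

    def test_empty_mask_is_identity(self, coding_aln):
        out = mask_columns(coding_aln, [])
        assert out.records == coding_aln.records
        assert out.partitions == coding_aln.partitions

    def test_codon_aligned_mask_preserves_frame(self, coding_aln):
        out = mask_columns(coding_aln, [(4, 9)])  # codons 2-3 of 4
        assert out.n_columns == 6
        assert out.partitions[0].coding
        assert out.records["s1"] == "ATGAAA"

    def test_frame_breaking_mask_rejected(self, coding_aln):
        with pytest.raises(AlignmentError, match="codon structure"):
            mask_columns(coding_aln, [(4, 5)])


class TestFlagPseudogenes:
    def test_internal_stop_flagged(self):
        aln = Alignment(
            {"ok": "ATGGCTGCTAAA", "bad": "ATGTAAGCTAAA"},
            partitions=[Partition("g", 0, 12, coding=True)],
        )
        flags = flag_pseudogenes(aln, aln.partitions[0])
        assert flags == [("bad", "internal stop at codon 2")]

    def test_final_codon_stop_not_flagged(self):
        aln = Alignment(
            {"s": "ATGGCTGCTTAA"}, partitions=[Partition("g", 0, 12, coding=True)]
        )
        assert flag_pseudogenes(aln, aln.partitions[0]) == []

    def test_frameshift_gap_flagged(self):
        aln = Alignment(
            {"fs": "ATG----GCTAAAGGG"[:12]},
            partitions=[Partition("g", 0, 12, coding=True)],
        )
        flags = flag_pseudogenes(aln, aln.partitions[0])
        assert flags == [("fs", "frameshift gap of length 4")]

    def test_codon_sized_gap_clean(self):
        aln = Alignment(
            {"s": "ATG---GCTAAA"}, partitions=[Partition("g", 0, 12, coding=True)]
        )
        assert flag_pseudogenes(aln, aln.partitions[0]) == []


class TestConcatenate:
    def test_union_labels_gap_filled(self):
        a = Alignment({"x": "AAAA", "y": "CCCC", "z": "GGGG"})
        b = Alignment({"x": "TTT", "y": "AAA", "w": "CCC"})
        cat = concatenate([a, b])
        assert cat.n_columns == 7
        assert cat.records["z"] == "GGGG---"
        assert cat.records["w"] == "----CCC"
        assert len(cat.partitions) == 2

    def test_single_input_is_identity(self):
        a = Alignment({"x": "ACGT"}, partitions=[Partition("g", 0, 4)])
        cat = concatenate([a])
        assert cat.records == a.records
        assert cat.n_columns == 4

    def test_conflicting_genomes_rejected(self):
        a = Alignment({"x": "AC"}, genome="nuclear")
        b = Alignment({"x": "AC"}, genome="chloroplast")
        with pytest.raises(AlignmentError, match="genome"):
            concatenate([a, b])

    def test_drop_partition_without_clade_coverage(self):
        gene1 = Alignment({"p1": "AAAA", "n1": "CCCC"})
        gene2 = Alignment({"n1": "GGG", "n2": "TTT"})  # no parasite coverage
        cat = concatenate([gene1, gene2], drop_uncovered_for=({"p1"}, {"n1"}))
        assert cat.n_columns == 4

    def test_column_count_conserved_and_content_preserved(self, rng):
        alns = []
        for k in range(3):
            ncol = int(rng.integers(3, 9))
            alns.append(
                Alignment(
                    {
                        f"t{j}": "".join(rng.choice(list("ACGT-"), ncol))
                        for j in range(1 + int(rng.integers(3)))
                    }
                )
            )
        cat = concatenate(alns)
        assert cat.n_columns == sum(a.n_columns for a in alns)
        offset = 0
        for a in alns:
            for lab, seq in a.records.items():
                assert cat.records[lab][offset : offset + a.n_columns] == seq
            offset += a.n_columns

    def test_mask_then_concat_commutes(self):
        a = Alignment({"x": "ACGTAC"})
        b = Alignment({"x": "GGTTCC"})
        left = concatenate([mask_columns(a, [(2, 3)]), b])
        right = mask_columns(concatenate([a, b]), [(2, 3)])
        assert left.records == right.records
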