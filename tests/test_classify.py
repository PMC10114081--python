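"""SBS96 / DBS78 / ID83 classification."""

from collections import Counter

import pytest

from sigdissect.channels import DBS78, ID83, SBS96
from sigdissect.classify import (
    classify_dbs,
    classify_indel,
    classify_record,
    classify_sbs,
    merge_adjacent,
    reverse_complement,
)
from sigdissect.variants import MutationRecord, left_align

from conftest import make_genome


class TestChannelTables:
    def test_axis_sizes(self):
        assert (len(SBS96), len(DBS78), len(ID83)) == (96, 78, 83)

    def test_sbs_order_starts_canonically(self):
        assert SBS96.channels[:4] == ("A[C>A]A", "A[C>A]C", "A[C>A]G", "A[C>A]T")

    def test_id83_blocks(self):
        assert ID83.channels[0] == "1:Del:C:0"
        assert "5:Del:M:5" in ID83
        assert sum(c.endswith("Del:M:1") or ":Del:M:" in c for c in ID83.channels) == 11


class TestClassifySbs:
    def test_pyrimidine_centred_direct(self):
        g = make_genome("AACAG")
        cm = classify_sbs(MutationRecord("chr1", 3, "C", "A"), g)
        assert cm.channel == "A[C>A]A"

    def test_purine_reverse_complemented(self):
        g = make_genome("ATGTA")
        cm = classify_sbs(MutationRecord("chr1", 3, "G", "T"), g)
        assert cm.channel == "A[C>A]A"

    def test_context_at_contig_end_unclassifiable(self):
        g = make_genome("CGT")
        cm = classify_sbs(MutationRecord("chr1", 1, "C", "A"), g)
        assert not cm.is_classified and cm.reason == "context_unavailable"

    def test_n_in_window_unclassifiable(self):
        g = make_genome("ANCTA")
        cm = classify_sbs(MutationRecord("chr1", 3, "C", "A"), g)
        assert not cm.is_classified

    def test_ref_mismatch_raises(self):
        g = make_genome("AACAG")
        with pytest.raises(ValueError, match="REF mismatch"):
            classify_sbs(MutationRecord("chr1", 3, "T", "A"), g)

    def test_exhaustive_enumeration_covers_96_twice(self):
        counts = Counter()
        for five in "ACGT":
            for centre in "ACGT":
                for three in "ACGT":
                    g = make_genome(f"A{five}{centre}{three}A")
                    for alt in "ACGT":
                        if alt == centre:
                            continue
                        cm = classify_sbs(MutationRecord("chr1", 3, centre, alt), g)
                        counts[cm.channel] += 1
        assert len(counts) == 96
        assert set(counts.values()) == {2}


class TestMergeAdjacent:
    def snv(self, pos, ref="C", alt="A"):
        return MutationRecord("chr1", pos, ref, alt, "c1")

    def test_adjacent_pair_becomes_doublet(self):
        d, iso, ex = merge_adjacent([self.snv(100), self.snv(101, "T", "G")])
        assert len(d) == 1 and iso == [] and ex == []
        assert (d[0].pos, d[0].ref, d[0].alt) == (100, "CT", "AG")

    def test_gap_of_one_not_merged(self):
        d, iso, ex = merge_adjacent([self.snv(100), self.snv(102)])
        assert d == [] and len(iso) == 2 and ex == []

    def test_run_of_three_excluded(self):
        d, iso, ex = merge_adjacent([self.snv(100), self.snv(101), self.snv(102)])
        assert d == [] and iso == []
        assert [len(r) for r in ex] == [3]

    def test_runs_do_not_cross_contigs(self):
        a = MutationRecord("chr1", 100, "C", "A")
        b = MutationRecord("chr2", 101, "C", "A")
        d, iso, ex = merge_adjacent([a, b])
        assert d == [] and len(iso) == 2

    def test_non_snv_rejected(self):
        with pytest.raises(ValueError):
            merge_adjacent([MutationRecord("chr1", 5, "CT", "C")])


class TestClassifyDbs:
    def test_canonical_identity(self):
        cm = classify_dbs(MutationRecord("chr1", 5, "CC", "AA"))
        assert cm.channel == "CC>AA"

    def test_reverse_complement_collapse(self):
        cm = classify_dbs(MutationRecord("chr1", 5, "GG", "TT"))
        assert cm.channel == "CC>AA"

    def test_partial_doublet_rejected(self):
        with pytest.raises(ValueError):
            classify_dbs(MutationRecord("chr1", 5, "CC", "CA"))

    def test_exhaustive_enumeration_collapses_to_78(self):
        channels = set()
        n_cases = 0
        for r0 in "ACGT":
            for r1 in "ACGT":
                for a0 in "ACGT":
                    for a1 in "ACGT":
                        if a0 == r0 or a1 == r1:
                            continue
                        n_cases += 1
                        cm = classify_dbs(MutationRecord("chr1", 5, r0 + r1, a0 + a1))
                        channels.add(cm.channel)
        assert n_cases == 144
        assert channels == set(DBS78.channels)


class TestClassifyIndel:
    def test_1bp_deletion_homopolymer_includes_deleted_base(self):
        # deleting one T from the TTTT run in CTTTTG: homopolymer length 4
        g = make_genome("ACTTTTGA")
        cm = classify_indel(MutationRecord("chr1", 2, "CT", "C"), g)
        assert cm.channel == "1:Del:T:3"

    def test_1bp_deletion_purine_collapsed(self):
        g = make_genome("TCAAAG")  # deleting an A == deleting a T on the other strand
        cm = classify_indel(MutationRecord("chr1", 2, "CA", "C"), g)
        assert cm.channel == "1:Del:T:2"

    def test_1bp_insertion_zero_repeat(self):
        g = make_genome("GCAGGA")  # insert T between CA and GG: no adjacent T
        cm = classify_indel(MutationRecord("chr1", 3, "A", "AT"), g)
        assert cm.channel == "1:Ins:T:0"

    def test_1bp_insertion_counts_existing_run_only(self):
        g = make_genome("GCTTTAG")
        cm = classify_indel(MutationRecord("chr1", 2, "C", "CT"), g)
        assert cm.channel == "1:Ins:T:3"

    def test_repeat_deletion_counts_remaining_copies(self):
        # delete CA from GCACACAT (left-aligned): two CA copies remain
        g = make_genome("GCACACAT")
        rec = left_align(MutationRecord("chr1", 1, "GCA", "G"), g)
        cm = classify_indel(rec, g)
        assert cm.channel == "2:Del:R:2"

    def test_microhomology_deletion(self):
        # delete TCTA; right flank begins TC (2 bp partial identity, no full copy)
        g = make_genome("GGTCTATCGGGG")
        cm = classify_indel(MutationRecord("chr1", 2, "GTCTA", "G"), g)
        assert cm.channel == "4:Del:M:2"

    def test_plain_deletion_no_repeat_no_mh(self):
        g = make_genome("GGACGTCCCC")
        cm = classify_indel(MutationRecord("chr1", 2, "GACGT", "G"), g)
        assert cm.channel == "4:Del:R:0"

    def test_insertion_next_to_existing_copies(self):
        g = make_genome("GGACACTT")
        cm = classify_indel(MutationRecord("chr1", 2, "G", "GAC"), g)
        assert cm.channel == "2:Ins:R:2"

    def test_too_long_unclassifiable(self):
        g = make_genome("G" + "ACGT" * 20)
        rec = MutationRecord("chr1", 1, "G" + "ACGT" * 13, "G")
        cm = classify_indel(rec, g)
        assert not cm.is_classified and cm.reason == "too_long"

    def test_size_and_mh_capped_at_5(self):
        frag = "ACGTCA"  # 6 bp deletion with 5 bp of flanking identity
        g = make_genome("GG" + frag + frag[:5] + "GGGG")
        cm = classify_indel(MutationRecord("chr1", 2, "G" + frag, "G"), g)
        assert cm.channel == "5:Del:M:5"

    def test_repeat_vs_microhomology_precedence(self):
        # one full flanking copy wins over any partial identity
        g = make_genome("GGACTACTAGG")
        cm = classify_indel(MutationRecord("chr1", 2, "GACT", "G"), g)
        assert cm.channel == "3:Del:R:1"


class TestClassifyRecord:
    def test_dispatch(self, genome_100kb):
        seq = genome_100kb.contigs["chr1"]
        pos = 500
        ref = seq[pos - 1]
        alt = "A" if ref != "A" else "C"
        cm = classify_record(MutationRecord("chr1", pos, ref, alt), genome_100kb)
        assert cm.axis is SBS96

    def test_partial_mnv_unclassifiable(self, genome_100kb):
        seq = genome_100kb.contigs["chr1"]
        ref = seq[99:101]
        alt = ("A" if ref[0] != "A" else "C") + ref[1]
        cm = classify_record(MutationRecord("chr1", 100, ref, alt), genome_100kb)
        assert not cm.is_classified and cm.reason == "partial_doublet"


def test_strand_collapse_involution(genome_100kb, rng):
    """Classifying an SNV on the mirrored genome gives the same channel."""
    seq = genome_100kb.contigs["chr1"]
    mirror = make_genome(reverse_complement(seq))
    L = len(seq)
    n = 0
    while n < 2000:
        pos = int(rng.integers(2, L))
        ref = seq[pos - 1]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        n += 1
        fwd = classify_sbs(MutationRecord("chr1", pos, ref, alt), genome_100kb)
        rev = classify_sbs(
            MutationRecord(
                "chr1", L - pos + 1, reverse_complement(ref), reverse_complement(alt)
            ),
            mirror,
        )
        assert fwd.channel == rev.channel
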