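import numpy as np
import pandas as pd
import pytest

from sigdissect.channels import SBS96
from sigdissect.variants import (
    MutationRecord,
    left_align,
    read_catalog,
    read_matrix,
    read_vcf,
    write_matrix,
    write_vcf,
)

from conftest import make_genome

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr1,length=1000>\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_lines(tmp_path, body: str):
    path = tmp_path / "x.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestRecordInvariants:
    def test_classification_flags(self):
        assert MutationRecord("c", 5, "C", "A").is_snv
        assert MutationRecord("c", 5, "C", "CT").is_insertion
        assert MutationRecord("c", 5, "CT", "C").is_deletion
        assert MutationRecord("c", 5, "CT", "AG").is_mnv

    @pytest.mark.parametrize("ref,alt", [("C", "C"), ("", "A"), ("C", ""), ("CX", "C")])
    def test_invalid_alleles(self, ref, alt):
        with pytest.raises(ValueError):
            MutationRecord("c", 5, ref, alt)

    def test_identity_key_excludes_clone(self):
        a = MutationRecord("c", 5, "C", "A", "clone1")
        b = MutationRecord("c", 5, "C", "A", "clone2")
        assert a.key == b.key


class TestReadVcf:
    def test_snv_parse(self, tmp_path):
        path = write_lines(tmp_path, "chr1\t101\t.\tC\tA\t50\tPASS\t.\n")
        recs = read_vcf(path, "c1")
        assert [r.key for r in recs] == [("chr1", 101, "C", "A")]
        assert recs[0].clone_id == "c1"

    def test_multiallelic_split(self, tmp_path):
        path = write_lines(tmp_path, "chr1\t101\t.\tC\tA,T\t50\tPASS\t.\n")
        recs = read_vcf(path, "c1")
        assert {r.alt for r in recs} == {"A", "T"}

    def test_anchored_deletion(self, tmp_path):
        path = write_lines(tmp_path, "chr1\t50\t.\tCT\tC\t50\t.\t.\n")
        (rec,) = read_vcf(path, "c1")
        assert rec.is_deletion and rec.pos == 50

    def test_filter_policy(self, tmp_path):
        body = (
            "chr1\t10\t.\tC\tA\t50\tPASS\t.\n"
            "chr1\t20\t.\tC\tA\t50\t.\t.\n"
            "chr1\t30\t.\tC\tA\t50\tLowQual\t.\n"
        )
        path = write_lines(tmp_path, body)
        assert [r.pos for r in read_vcf(path, "c")] == [10, 20]

    def test_symbolic_allele_dropped(self, tmp_path):
        path = write_lines(tmp_path, "chr1\t10\t.\tC\t<DEL>\t50\tPASS\t.\n")
        assert read_vcf(path, "c") == []


class TestWriteVcf:
    RECORDS = [
        MutationRecord("chr1", 50, "CT", "C", "c1"),
        MutationRecord("chr1", 10, "C", "A", "c1"),
        MutationRecord("chr2", 5, "G", "GAT", "c1"),
    ]
    LENGTHS = {"chr1": 1000, "chr2": 500}

    def test_round_trip_identity_key(self, tmp_path):
        path = tmp_path / "out.vcf"
        write_vcf(self.RECORDS, path, self.LENGTHS)
        back = read_vcf(path, "c1")
        assert sorted(r.key for r in back) == sorted(r.key for r in self.RECORDS)

    def test_sorted_output(self, tmp_path):
        path = tmp_path / "out.vcf"
        write_vcf(self.RECORDS, path, self.LENGTHS)
        back = read_vcf(path, "c1")
        assert [(r.contig, r.pos) for r in back] == [("chr1", 10), ("chr1", 50), ("chr2", 5)]

    def test_empty_record_list(self, tmp_path):
        path = tmp_path / "out.vcf"
        write_vcf([], path, self.LENGTHS)
        assert read_vcf(path, "c1") == []

    def test_unknown_contig_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_vcf([MutationRecord("chrX", 1, "C", "A")], tmp_path / "o.vcf", self.LENGTHS)


class TestLeftAlign:
    def test_deletion_shifts_through_repeat(self):
        g = make_genome("GCACACAT")
        # deleting the last CA is equivalent to deleting the first
        rec = left_align(MutationRecord("chr1", 5, "ACA", "A"), g)
        assert (rec.pos, rec.ref, rec.alt) == (1, "GCA", "G")

    def test_insertion_shifts_through_homopolymer(self):
        g = make_genome("CTTTG")
        rec = left_align(MutationRecord("chr1", 4, "T", "TT"), g)
        assert (rec.pos, rec.ref, rec.alt) == (1, "C", "CT")

    def test_already_left_aligned_unchanged(self):
        g = make_genome("GCATT")
        rec = MutationRecord("chr1", 2, "CA", "C")
        assert left_align(rec, g) == rec

    def test_ref_mismatch_rejected(self):
        g = make_genome("GCATT")
        with pytest.raises(ValueError, match="REF mismatch"):
            left_align(MutationRecord("chr1", 2, "TT", "T"), g)

    def test_alignment_preserves_edit(self):
        # applying the shifted deletion yields the same sequence
        g = make_genome("AGCGCGCT")
        rec = MutationRecord("chr1", 5, "CGC", "C")
        shifted = left_align(rec, g)
        s = g.contigs["chr1"]

        def apply(r):
            return s[: r.pos - 1] + r.alt + s[r.pos - 1 + len(r.ref) :]

        assert apply(rec) == apply(shifted)
        assert shifted.pos <= rec.pos


class TestCatalogIO:
    def make_catalog_frame(self, names=("SigA", "SigB"), seed=0):
        rng = np.random.default_rng(seed)
        data = rng.random((96, len(names)))
        data /= data.sum(axis=0)
        return pd.DataFrame(data, index=list(SBS96.channels), columns=list(names))

    def test_read_normalizes(self, tmp_path):
        df = self.make_catalog_frame()
        path = tmp_path / "cat.tsv"
        df.to_csv(path, sep="\t")
        cat = read_catalog(path)
        assert np.allclose(cat.vectors.sum(axis=0), 1.0, atol=1e-9)
        assert cat.names == ("SigA", "SigB")

    def test_row_order_invariance(self, tmp_path):
        df = self.make_catalog_frame(seed=3)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        df.to_csv(a, sep="\t")
        df.sample(frac=1.0, random_state=5).to_csv(b, sep="\t")
        ca, cb = read_catalog(a), read_catalog(b)
        assert np.allclose(ca.vectors, cb.vectors)

    def test_missing_channel_rejected(self, tmp_path):
        df = self.make_catalog_frame().iloc[:-1]
        path = tmp_path / "cat.tsv"
        df.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="channel"):
            read_catalog(path)

    def test_bad_column_sum_rejected(self, tmp_path):
        df = self.make_catalog_frame() * 2.0
        path = tmp_path / "cat.tsv"
        df.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="sum to 1"):
            read_catalog(path)

    def test_matrix_round_trip(self, tmp_path):
        df = self.make_catalog_frame(names=("clone1", "clone2", "clone3"), seed=9) * 100
        path = tmp_path / "m.tsv"
        write_matrix(df, path)
        back = read_matrix(path)
        assert np.allclose(back.values, df.values)
        assert list(back.index) == list(SBS96.channels)
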