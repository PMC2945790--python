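"""Converter: allele arithmetic oracle, VCF round trips, dialects."""

import io
import itertools

import pytest

from gvftools import (
    TableDialect,
    alleles_to_gvf,
    generate_vcf,
    gvf_to_vcf,
    table_to_gvf,
    validate,
    vcf_to_gvf,
)
from gvftools.errors import ConversionError

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA00001
"""


def _vcf(*rows):
    return io.StringIO(VCF_HEADER + "\n".join(rows) + "\n")


def _apply_vcf(genome, pos, ref, alt):
    """Apply a VCF-style edit to a sequence string (1-based pos)."""
    assert genome[pos - 1 : pos - 1 + len(ref)] == ref
    return genome[: pos - 1] + alt + genome[pos - 1 + len(ref) :]


def _apply_gvf(genome, start, end, reference_seq, token):
    """Apply one GVF allele to a sequence string (1-based inclusive)."""
    if reference_seq == "-":  # insertion after the anchor base
        assert start == end
        return genome[:start] + token + genome[start:]
    assert genome[start - 1 : end] == reference_seq
    replacement = "" if token == "-" else token
    return genome[: start - 1] + replacement + genome[end:]


class TestAlleleArithmetic:
    def test_snv_mapping(self):
        assert alleles_to_gvf("chr1", 12345, "G", ("A",)) == (
            "SNV", 12345, 12345, "G", ["A"],
        )

    def test_deletion_prefix_trim(self):
        # REF=GA ALT=G at p: deletion of the base at p+1
        assert alleles_to_gvf("chr1", 100, "GA", ("G",)) == (
            "deletion", 101, 101, "A", ["-"],
        )

    def test_insertion_anchor(self):
        assert alleles_to_gvf("chr1", 100, "G", ("GTT",)) == (
            "insertion", 100, 100, "-", ["TT"],
        )

    def test_identical_alleles_degenerate(self):
        with pytest.raises(ConversionError):
            alleles_to_gvf("chr1", 100, "G", ("G",))

    def test_all_short_pairs_against_edit_oracle(self):
        """For every REF/ALT pair of length 1-3, applying the GVF record
        to a genome must produce the same sequence as applying the VCF
        edit — an oracle independent of the trimming arithmetic."""
        genome = "TTTTACGTACGTACGTTTTT"
        pos = 5
        alphabet = "ACG"
        pool = [
            "".join(p)
            for n in (1, 2, 3)
            for p in itertools.product(alphabet, repeat=n)
        ]
        checked = 0
        for ref, alt in itertools.product(pool, repeat=2):
            if ref == alt or genome[pos - 1 : pos - 1 + len(ref)] != ref:
                continue
            so_type, start, end, reference_seq, tokens = alleles_to_gvf(
                "chr1", pos, ref, (alt,)
            )
            assert _apply_gvf(genome, start, end, reference_seq, tokens[0]) == \
                _apply_vcf(genome, pos, ref, alt), (ref, alt)
            checked += 1
        assert checked > 100


class TestVcfToGvf:
    def test_het_snv(self):
        result = vcf_to_gvf(
            _vcf("chr1\t12345\t.\tG\tA\t.\tPASS\t.\tGT\t0/1"),
            provenance={"genome_build": "NCBI B36"},
        )
        (rec,) = result.document.records
        assert rec.so_type == "SNV"
        assert rec.start == rec.end == 12345
        assert rec.attributes.reference_seq == "G"
        assert rec.attributes.variant_seq == ["A"]
        assert rec.attributes.genotype == "heterozygous"

    @pytest.mark.parametrize(
        "gt,expected",
        [("1/1", "homozygous"), ("0/1", "heterozygous"), ("1", "hemizygous")],
    )
    def test_gt_mapping(self, gt, expected):
        result = vcf_to_gvf(_vcf(f"chr1\t10\t.\tG\tA\t.\tPASS\t.\tGT\t{gt}"))
        assert result.document.records[0].attributes.genotype == expected

    def test_reads_from_ad_and_dp(self):
        result = vcf_to_gvf(
            _vcf("chr1\t10\t.\tG\tA,T\t.\tPASS\t.\tGT:AD:DP\t1/2:5,34,23:62")
        )
        a = result.document.records[0].attributes
        assert a.variant_reads == [34, 23]
        assert a.total_reads == 62

    def test_multiallelic_becomes_one_record(self):
        result = vcf_to_gvf(_vcf("chr1\t10\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2"))
        (rec,) = result.document.records
        assert rec.attributes.variant_seq == ["A", "T"]

    def test_symbolic_alt_skipped_and_counted(self):
        result = vcf_to_gvf(
            _vcf(
                "chr1\t10\t.\tG\tA\t.\tPASS\t.\tGT\t0/1",
                "chr1\t20\t.\tG\t<DEL>\t.\tPASS\t.\tGT\t0/1",
            )
        )
        assert result.n_input == 2
        assert result.n_converted == 1
        assert result.n_skipped == 1
        assert result.n_converted == result.n_input - result.n_skipped

    def test_rsid_preserved_as_dbxref(self):
        result = vcf_to_gvf(_vcf("chr1\t10\trs10399749\tG\tA\t.\tPASS\t.\tGT\t0/1"))
        assert result.document.records[0].attributes.extra["Dbxref"] == [
            "dbSNP:rs10399749"
        ]

    def test_provenance_pragmas_emitted(self):
        result = vcf_to_gvf(
            _vcf("chr1\t10\t.\tG\tA\t.\tPASS\t.\tGT\t0/1"),
            provenance={
                "genome_build": "NCBI B36",
                "technology_platform": {"Source": "x", "Platform_name": "Illumina"},
            },
        )
        p = result.document.pragmas
        assert p.genome_build == "NCBI B36"
        assert p.technology_platforms[0]["Platform_name"] == "Illumina"

    def test_converted_records_validate_cleanly(self, ontology):
        vcf_text, _ = generate_vcf(3, 30)
        result = vcf_to_gvf(
            io.StringIO(vcf_text), provenance={"genome_build": "NCBI B36"}
        )
        assert validate(result.document, ontology).n_errors == 0


class TestRoundTrip:
    def test_vcf_gvf_vcf_preserves_sites(self):
        vcf_text, reference = generate_vcf(11, 20)
        fwd = vcf_to_gvf(io.StringIO(vcf_text))
        assert fwd.n_skipped == 0
        back = gvf_to_vcf(fwd.document, reference=reference)
        assert back.n_skipped == 0

        def sites(text):
            return [
                tuple(line.split("\t")[:2]) + tuple(line.split("\t")[3:5])
                for line in text.splitlines()
                if line and not line.startswith("#")
            ]

        assert sites(back.text) == sites(vcf_text)

    def test_idempotent_normalization(self):
        vcf_text, reference = generate_vcf(13, 25)
        once = vcf_to_gvf(io.StringIO(vcf_text))
        there = gvf_to_vcf(once.document, reference=reference)
        twice = vcf_to_gvf(io.StringIO(there.text))
        assert twice.document.records == once.document.records

    def test_abbreviated_sequence_skipped(self):
        from gvftools import Attributes, GvfDocument, GvfRecord

        doc = GvfDocument()
        doc.pragmas.genome_build = "b x"
        doc.records.append(
            GvfRecord(
                "chr1", "x", "insertion", 10, 10,
                attributes=Attributes(id="i", reference_seq="-", variant_seq=["~"]),
            )
        )
        result = gvf_to_vcf(doc)
        assert result.n_skipped == 1
        assert result.n_converted == 0

    def test_het_two_allele_record_gives_two_alts(self):
        vcf_in = _vcf("chr1\t10\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2")
        fwd = vcf_to_gvf(vcf_in)
        back = gvf_to_vcf(fwd.document)
        data = [l for l in back.text.splitlines() if not l.startswith("#")][0]
        assert data.split("\t")[4] == "A,T"
        assert "1/2" in data

    def test_deletion_without_reference_skipped(self):
        fwd = vcf_to_gvf(_vcf("chr1\t10\t.\tGA\tG\t.\tPASS\t.\tGT\t0/1"))
        back = gvf_to_vcf(fwd.document, reference=None)
        assert back.n_skipped == 1


class TestTableToGvf:
    DIALECT = TableDialect(columns={0: "seqid", 1: "pos", 2: "ref", 3: "alt"})

    def test_agrees_with_vcf_converter(self):
        table = table_to_gvf(["chr1\t12345\tG\tA"], self.DIALECT)
        vcf = vcf_to_gvf(_vcf("chr1\t12345\t.\tG\tA\t.\tPASS\t.\tGT\t./."))
        t, v = table.document.records[0], vcf.document.records[0]
        assert (t.seqid, t.so_type, t.start, t.end) == (v.seqid, v.so_type, v.start, v.end)
        assert t.attributes.variant_seq == v.attributes.variant_seq
        assert t.attributes.reference_seq == v.attributes.reference_seq

    def test_empty_input(self):
        result = table_to_gvf([], self.DIALECT)
        assert len(result.document) == 0

    def test_comma_alt_field(self):
        result = table_to_gvf(["chr1\t10\tG\tA,T"], self.DIALECT)
        assert result.document.records[0].attributes.variant_seq == ["A", "T"]

    def test_short_row_skipped_with_diagnostic(self):
        result = table_to_gvf(["chr1\t10\tG"], self.DIALECT)
        assert result.n_skipped == 1
        assert "row 1" in result.warnings[0]

    def test_id_naming_convention(self):
        result = table_to_gvf(
            ["chr1\t12345\tG\tA"],
            TableDialect(columns={0: "seqid", 1: "pos", 2: "ref", 3: "alt"}, source="Soap"),
        )
        assert result.document.records[0].attributes.id == "chr1:Soap:SNV:12345"

    def test_genotype_column(self):
        dialect = TableDialect(
            columns={0: "seqid", 1: "pos", 2: "ref", 3: "alt", 4: "genotype"}
        )
        result = table_to_gvf(["chr1\t10\tG\tA\thet"], dialect)
        assert result.document.records[0].attributes.genotype == "heterozygous"

    def test_dialect_requires_core_roles(self):
        with pytest.raises(ConversionError):
            TableDialect(columns={0: "seqid", 1: "pos"})
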