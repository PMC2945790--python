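"""Annotator: interval index vs linear scan, all-pairs effect oracle."""

import copy
import io
import random

import pytest

from gvftools import (
    annotate,
    build_feature_index,
    generate_document,
    generate_gff3,
    validate,
)
from gvftools.errors import ConfigurationError

SIMPLE_GFF = """\
##gff-version 3
chr1\tx\tgene\t100\t900\t.\t+\t.\tID=g1
chr1\tx\tmRNA\t100\t900\t.\t+\t.\tID=NM_012345
chr1\tx\tmRNA\t150\t950\t.\t-\t.\tID=NM_098765
"""


def _overlaps(s1, e1, s2, e2):
    return s1 <= e2 and s2 <= e1


class TestFeatureIndex:
    def test_index_size(self):
        idx = build_feature_index(io.StringIO(SIMPLE_GFF))
        assert len(idx) == 3

    def test_overlapping_pair_both_retrievable(self):
        idx = build_feature_index(io.StringIO(SIMPLE_GFF))
        hits = idx.overlapping("chr1", 200, 200)
        assert {f.feature_id for f in hits} == {"g1", "NM_012345", "NM_098765"}

    def test_feature_without_id_gets_surrogate(self):
        gff = "##gff-version 3\nchr1\tx\texon\t5\t10\t.\t+\t.\tNote=anonymous\n"
        idx = build_feature_index(io.StringIO(gff))
        assert len(idx) == 1
        assert idx.warnings
        assert idx.features[0].feature_id.startswith("exon")

    def test_stabbing_queries_match_linear_scan(self):
        """200 random features: every stabbing query equals the naive scan."""
        gff = generate_gff3(seed=21, n_features=200, region_length=50_000)
        idx = build_feature_index(io.StringIO(gff))
        rng = random.Random(99)
        for _ in range(300):
            seqid = ("chr1", "chr2", "chr3", "chrX")[rng.randrange(4)]
            s = 1 + rng.randrange(60_000)
            e = s + rng.randrange(500)
            expected = {
                f.feature_id
                for f in idx.features
                if f.seqid == seqid and _overlaps(s, e, f.start, f.end)
            }
            got = {f.feature_id for f in idx.overlapping(seqid, s, e)}
            assert got == expected

    def test_gffutils_cross_check(self, tmp_path):
        """Independent parse of the same GFF3 with gffutils agrees on the
        indexed intervals."""
        gffutils = pytest.importorskip("gffutils")
        gff = generate_gff3(seed=4, n_features=50)
        path = tmp_path / "f.gff3"
        path.write_text(gff)
        db = gffutils.create_db(str(path), ":memory:")
        ours = {(f.feature_id, f.seqid, f.start, f.end) for f in
                build_feature_index(io.StringIO(gff)).features}
        theirs = {(f.id, f.seqid, f.start, f.end) for f in db.all_features()}
        assert ours == theirs


class TestAnnotate:
    def test_two_mrnas_merge_into_one_entry(self, ontology):
        from gvftools import parse_text

        doc = parse_text(
            "##gff-version 3\n##genome-build b x\n"
            "chr1\tx\tSNV\t200\t200\t.\t+\t.\tID=r1;Variant_seq=A;Reference_seq=G\n"
        )
        idx = build_feature_index(io.StringIO(SIMPLE_GFF))
        annotate(doc, idx, effect_map={"mRNA": "non_synonymous_codon"}, ontology=ontology)
        effects = doc.records[0].attributes.variant_effects
        mrna = [e for e in effects if e.feature_type == "mRNA"]
        assert len(mrna) == 1
        assert mrna[0].effect_term == "non_synonymous_codon"
        assert set(mrna[0].feature_ids) == {"NM_012345", "NM_098765"}
        assert mrna[0].seq_index == 0

    def test_unindexed_seqid_leaves_record_unchanged(self, ontology):
        doc = generate_document(2, 5)
        idx = build_feature_index(io.StringIO("##gff-version 3\n"))
        before = copy.deepcopy(doc)
        annotate(doc, idx, ontology=ontology)
        assert doc == before

    def test_matches_all_pairs_oracle(self, ontology):
        """100 variants x 100 features: the annotation equals brute-force
        all-pairs intersection."""
        doc = generate_document(seed=31, n_records=100)
        gff = generate_gff3(seed=32, n_features=100)
        idx = build_feature_index(io.StringIO(gff))
        annotate(doc, idx, ontology=ontology)
        for rec in doc.records:
            s, e = rec.start, rec.end
            if rec.is_insertion:
                e = s
            expected = set()
            n_alleles = len(rec.attributes.variant_seq) if rec.attributes.variant_seq else 1
            for f in idx.features:
                if f.seqid == rec.seqid and _overlaps(s, e, f.start, f.end):
                    for i in range(n_alleles):
                        expected.add(("sequence_variant", i, f.feature_type, f.feature_id))
            got = {
                (eff.effect_term, eff.seq_index, eff.feature_type, fid)
                for eff in rec.attributes.variant_effects
                for fid in eff.feature_ids
            }
            assert got == expected, rec.attributes.id

    def test_annotated_document_still_validates(self, ontology):
        doc = generate_document(seed=31, n_records=60)
        idx = build_feature_index(io.StringIO(generate_gff3(seed=32, n_features=80)))
        annotate(doc, idx, ontology=ontology)
        assert validate(doc, ontology).n_errors == 0

    def test_idempotent(self, ontology):
        doc = generate_document(seed=31, n_records=60)
        idx = build_feature_index(io.StringIO(generate_gff3(seed=32, n_features=80)))
        annotate(doc, idx, ontology=ontology)
        once = copy.deepcopy(doc)
        annotate(doc, idx, ontology=ontology)
        assert doc == once

    def test_additive_preserves_existing_effects(self, ontology):
        from gvftools import parse_text

        doc = parse_text(
            "##gff-version 3\n##genome-build b x\n"
            "chr1\tx\tSNV\t200\t200\t.\t+\t.\t"
            "ID=r1;Variant_seq=A;Variant_effect=intergenic_variant 0 gene old1\n"
        )
        idx = build_feature_index(io.StringIO(SIMPLE_GFF))
        annotate(doc, idx, ontology=ontology)
        effects = doc.records[0].attributes.variant_effects
        assert any(e.effect_term == "intergenic_variant" for e in effects)
        assert any(e.feature_type == "mRNA" for e in effects)

    def test_effect_map_outside_branch_rejected(self, ontology):
        doc = generate_document(2, 3)
        idx = build_feature_index(io.StringIO(SIMPLE_GFF))
        with pytest.raises(ConfigurationError):
            annotate(doc, idx, effect_map={"mRNA": "exon"}, ontology=ontology)
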