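"""Validator rule set: examples, determinism, monotonicity."""

import copy

from gvftools import generate_document, parse_text, serialize, validate


def _gvf(body_lines, pragmas=("##gff-version 3", "##genome-build NCBI B36")):
    return parse_text("\n".join([*pragmas, *body_lines]) + "\n")


def _line(attrs, so_type="SNV", start=100, end=100):
    return f"chr1\tx\t{so_type}\t{start}\t{end}\t.\t+\t.\t{attrs}"


class TestRules:
    def test_well_formed_document_is_clean(self, trio_doc, ontology):
        report = validate(trio_doc, ontology)
        assert report.n_errors == 0
        assert report.n_warnings == 0
        assert report.is_valid

    def test_missing_id_fires_r1(self, ontology):
        report = validate(_gvf([_line("Reference_seq=G;Variant_seq=A")]), ontology)
        assert [d.rule_id for d in report if d.severity == "error"] == ["R1"]

    def test_duplicate_id_fires_r1(self, ontology):
        doc = _gvf([_line("ID=r1"), _line("ID=r1", start=200, end=200)])
        assert "R1" in validate(doc, ontology).rules_fired()

    def test_missing_genome_build_fires_r2(self, ontology):
        doc = _gvf([_line("ID=r1")], pragmas=("##gff-version 3",))
        assert "R2" in validate(doc, ontology).rules_fired()

    def test_feature_term_in_type_column_fires_r3(self, ontology):
        doc = _gvf([_line("ID=r1", so_type="mRNA")])
        assert "R3" in validate(doc, ontology).rules_fired()

    def test_frequency_above_one_fires_r5(self, ontology):
        doc = _gvf([_line("ID=r1;Variant_seq=A;Variant_freq=1.5")])
        assert "R5" in validate(doc, ontology).rules_fired()

    def test_effect_index_boundary_fires_r6(self, ontology):
        # two alleles: valid indices are exactly 0 and 1
        ok = _gvf(
            [_line("ID=r1;Variant_seq=A,T;Variant_effect=sequence_variant 1 mRNA m1")]
        )
        assert "R6" not in validate(ok, ontology).rules_fired()
        bad = _gvf(
            [_line("ID=r1;Variant_seq=A,T;Variant_effect=sequence_variant 2 mRNA m1")]
        )
        assert "R6" in validate(bad, ontology).rules_fired()

    def test_effect_terms_must_match_branches(self, ontology):
        swapped = _gvf([_line("ID=r1;Variant_seq=A;Variant_effect=mRNA 0 mRNA m1")])
        assert "R6" in validate(swapped, ontology).rules_fired()

    def test_genotype_outside_enumeration_fires_r7(self, ontology):
        doc = _gvf([_line("ID=r1;Genotype=diploid")])
        assert "R7" in validate(doc, ontology).rules_fired()

    def test_end_before_start_fires_r8(self, ontology):
        doc = _gvf([_line("ID=r1", so_type="deletion", start=10, end=8)])
        assert "R8" in validate(doc, ontology).rules_fired()

    def test_insertion_signature_exempt_from_r8(self, ontology):
        doc = _gvf([_line("ID=r1;Reference_seq=-;Variant_seq=ACG", so_type="insertion")])
        assert "R8" not in validate(doc, ontology).rules_fired()

    def test_bad_file_date_fires_r9(self, ontology):
        doc = _gvf(
            [_line("ID=r1")],
            pragmas=("##gff-version 3", "##genome-build b x", "##file-date 26-08-2010"),
        )
        assert "R9" in validate(doc, ontology).rules_fired()

    def test_inconsistent_genotype_warns_r10(self, ontology):
        doc = _gvf([_line("ID=r1;Variant_seq=A,T;Genotype=homozygous")])
        report = validate(doc, ontology)
        (diag,) = report.by_rule("R10")
        assert diag.severity == "warning"
        assert report.is_valid  # warnings do not invalidate

    def test_unknown_tags_warn_r11(self, ontology):
        doc = _gvf([_line("ID=r1;Zzz=1")])
        assert "R11" in validate(doc, ontology).rules_fired()

    def test_gff3_inherited_tags_do_not_warn(self, ontology):
        doc = _gvf([_line("ID=r1;Alias=rs123;Dbxref=dbSNP:rs123")])
        assert validate(doc, ontology).rules_fired() == set()

    def test_non_iupac_sequence_fires_r12(self, ontology):
        doc = _gvf([_line("ID=r1;Variant_seq=J")])
        (diag,) = validate(doc, ontology).by_rule("R12")
        assert diag.severity == "error"

    def test_iupac_ambiguity_code_warns_r12(self, ontology):
        doc = _gvf([_line("ID=r1;Variant_seq=R")])
        (diag,) = validate(doc, ontology).by_rule("R12")
        assert diag.severity == "warning"

    def test_absent_optional_tags_never_diagnosed(self, ontology):
        doc = _gvf([_line("ID=r1")])
        assert len(validate(doc, ontology)) == 0

    def test_total_reads_below_variant_reads_warns(self, ontology):
        doc = _gvf([_line("ID=r1;Variant_seq=A;Variant_reads=40;Total_reads=30")])
        (diag,) = validate(doc, ontology).by_rule("R13")
        assert diag.severity == "warning"

    def test_diagnostics_are_line_tagged(self, ontology):
        doc = _gvf([_line("ID=r1"), _line("ID=r1", start=5, end=5)])
        dup = validate(doc, ontology).by_rule("R1")[0]
        assert dup.line == 4


class TestReportProperties:
    def test_determinism(self, valid_doc, ontology):
        doc = parse_text(serialize(valid_doc))
        r1 = validate(doc, ontology)
        r2 = validate(parse_text(serialize(valid_doc)), ontology)
        assert r1.diagnostics == r2.diagnostics

    def test_monotonic_under_record_deletion(self, ontology):
        """Deleting records never introduces diagnostics about the rest."""
        from gvftools import break_document

        doc = break_document(generate_document(3, 30), "R5", seed=1)
        full = {
            (d.rule_id, d.line, d.message) for d in validate(doc, ontology)
        }
        for drop in (0, len(doc.records) // 2, len(doc.records) - 1):
            smaller = copy.deepcopy(doc)
            del smaller.records[drop]
            small = {
                (d.rule_id, d.line, d.message) for d in validate(smaller, ontology)
            }
            assert small <= full

    def test_tsv_and_json_rendering(self, ontology):
        doc = _gvf([_line("ID=r1;Variant_seq=A;Variant_freq=2.0")])
        report = validate(doc, ontology)
        assert "R5" in report.to_tsv()
        import json

        payload = json.loads(report.to_json())
        assert payload["valid"] is False
        assert payload["n_errors"] == 1
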