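"""The GVF rule set: validate a parsed document into a diagnostic report.

Every problem becomes an ordered, line-tagged diagnostic; nothing raises.
A document is *valid* iff no error-severity diagnostic fired.  Severity
policy: absence of an optional tag is never diagnosed, malformation of a
present tag always is; checks the format text leaves arithmetic-ambiguous
(genotype vs. allele count, total vs. per-allele read counts) are
warnings.

Rules
-----
R1   ID present and unique within the file (error)
R2   genome-build pragma present (error)
R3   type column in the sequence_alteration branch (error)
R4   Variant_reads / Variant_freq aligned with Variant_seq (error)
R5   Variant_freq values within [0, 1] (error)
R6   Variant_effect well-typed: consequence in sequence_variant branch,
     feature type in sequence_feature branch, allele index in range (error)
R7   Genotype in {heterozygous, homozygous, hemizygous} (error)
R8   start >= 1 and end >= start; the insertion signature
     (start == end with Reference_seq '-') is exempt by construction (error)
R9   file-date pragma is ISO 8601 YYYY-MM-DD (error)
R10  genotype consistent with the distinct-allele count (warning)
R11  unknown pragma keyword or attribute tag (warning)
R12  sequence tokens drawn from IUPAC codes plus '-' and '~'; IUPAC
     ambiguity codes outside A/C/G/T/N warn, anything else errors
R13  Total_reads at least max(Variant_reads) (warning)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

from .errors import UnknownTermError
from .model import (
    GENOTYPES,
    GFF3_ATTRIBUTE_TAGS,
    GFF3_PRAGMAS,
    GVF_PRAGMAS,
    GvfDocument,
    GvfRecord,
    IUPAC_CODES,
    genotype_consistency,
    is_iso_date,
)
from .ontology import Ontology

ERROR = "error"
WARNING = "warning"

_PLAIN_CODES = frozenset("ACGTN")
_TOKEN_OK = IUPAC_CODES | {"-", "~"}


@dataclass(frozen=True)
class Diagnostic:
    severity: str
    rule_id: str
    line: int | None
    message: str

    def as_tsv(self) -> str:
        line = "" if self.line is None else str(self.line)
        return f"{self.severity}\t{self.rule_id}\t{line}\t{self.message}"


@dataclass
class ValidationReport:
    """Ordered diagnostics plus severity counts."""

    diagnostics: list[Diagnostic] = field(default_factory=list)

    def __iter__(self) -> Iterator[Diagnostic]:
        return iter(self.diagnostics)

    def __len__(self) -> int:
        return len(self.diagnostics)

    @property
    def n_errors(self) -> int:
        return sum(d.severity == ERROR for d in self.diagnostics)

    @property
    def n_warnings(self) -> int:
        return sum(d.severity == WARNING for d in self.diagnostics)

    @property
    def is_valid(self) -> bool:
        return self.n_errors == 0

    def rules_fired(self) -> set[str]:
        return {d.rule_id for d in self.diagnostics}

    def by_rule(self, rule_id: str) -> list[Diagnostic]:
        return [d for d in self.diagnostics if d.rule_id == rule_id]

    def to_tsv(self) -> str:
        header = "severity\trule\tline\tmessage"
        return "\n".join([header, *(d.as_tsv() for d in self.diagnostics)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "valid": self.is_valid,
                "n_errors": self.n_errors,
                "n_warnings": self.n_warnings,
                "diagnostics": [
                    {
                        "severity": d.severity,
                        "rule": d.rule_id,
                        "line": d.line,
                        "message": d.message,
                    }
                    for d in self.diagnostics
                ],
            },
            indent=2,
        )


class _Emitter:
    def __init__(self) -> None:
        self.report = ValidationReport()

    def __call__(self, severity: str, rule: str, line: int | None, message: str) -> None:
        self.report.diagnostics.append(Diagnostic(severity, rule, line, message))


def _in_branch(ontology: Ontology, term: str, branch: str) -> bool:
    try:
        return branch in ontology.branches(term)
    except UnknownTermError:
        return False


def _check_seq_token(emit: _Emitter, token: str, what: str, line: int | None) -> None:
    if token in ("-", "~"):
        return
    bad = sorted({c for c in token if c not in _TOKEN_OK})
    if bad:
        emit(
            ERROR, "R12", line,
            f"{what} contains non-IUPAC character(s) {''.join(bad)!r}",
        )
        return
    ambiguous = sorted({c for c in token if c not in _PLAIN_CODES})
    if ambiguous:
        emit(
            WARNING, "R12", line,
            f"{what} uses IUPAC ambiguity code(s) {''.join(ambiguous)!r}",
        )


def _validate_record(emit: _Emitter, rec: GvfRecord, ontology: Ontology) -> None:
    a = rec.attributes
    line = rec.line

    if not a.id:
        emit(ERROR, "R1", line, "record lacks the mandatory ID attribute")

    if not _in_branch(ontology, rec.so_type, "sequence_alteration"):
        emit(
            ERROR, "R3", line,
            f"type {rec.so_type!r} is not in the sequence_alteration branch",
        )

    if a.variant_seq is not None:
        for lst, tag in ((a.variant_reads, "Variant_reads"), (a.variant_freq, "Variant_freq")):
            if lst is not None and len(lst) != len(a.variant_seq):
                emit(
                    ERROR, "R4", line,
                    f"{tag} has {len(lst)} value(s) but Variant_seq has "
                    f"{len(a.variant_seq)}",
                )

    if a.variant_freq is not None:
        for v in a.variant_freq:
            if not 0.0 <= v <= 1.0:
                emit(ERROR, "R5", line, f"Variant_freq {v} outside [0, 1]")

    for eff in a.variant_effects:
        if not _in_branch(ontology, eff.effect_term, "sequence_variant"):
            emit(
                ERROR, "R6", line,
                f"Variant_effect term {eff.effect_term!r} is not in the "
                "sequence_variant branch",
            )
        if not _in_branch(ontology, eff.feature_type, "sequence_feature"):
            emit(
                ERROR, "R6", line,
                f"Variant_effect feature type {eff.feature_type!r} is not in "
                "the sequence_feature branch",
            )
        if a.variant_seq is not None and eff.seq_index >= len(a.variant_seq):
            emit(
                ERROR, "R6", line,
                f"Variant_effect index {eff.seq_index} out of range for "
                f"{len(a.variant_seq)} variant sequence(s)",
            )

    if a.genotype is not None and a.genotype not in GENOTYPES:
        emit(
            ERROR, "R7", line,
            f"Genotype {a.genotype!r} not in {sorted(GENOTYPES)}",
        )

    if rec.start < 1:
        emit(ERROR, "R8", line, f"start {rec.start} is not positive")
    if rec.end < rec.start:
        emit(ERROR, "R8", line, f"end {rec.end} < start {rec.start}")

    if not genotype_consistency(a):
        emit(
            WARNING, "R10", line,
            f"Genotype {a.genotype!r} inconsistent with "
            f"{len(set(a.variant_seq or []))} distinct variant sequence(s)",
        )

    for tag in a.extra:
        if tag not in GFF3_ATTRIBUTE_TAGS:
            emit(WARNING, "R11", line, f"unrecognized attribute tag {tag!r}")

    if a.variant_seq is not None:
        for i, token in enumerate(a.variant_seq):
            _check_seq_token(emit, token, f"Variant_seq[{i}]", line)
    if a.reference_seq is not None:
        _check_seq_token(emit, a.reference_seq, "Reference_seq", line)

    if a.total_reads is not None and a.variant_reads:
        if a.total_reads < max(a.variant_reads):
            emit(
                WARNING, "R13", line,
                f"Total_reads {a.total_reads} < max Variant_reads "
                f"{max(a.variant_reads)}",
            )


def validate(document: GvfDocument, ontology: Ontology) -> ValidationReport:
    """Apply the full GVF rule set; single pass, diagnostics in file order."""
    emit = _Emitter()
    p = document.pragmas

    if not p.genome_build:
        emit(ERROR, "R2", None, "mandatory genome-build pragma is missing")
    if p.file_date is not None and not is_iso_date(p.file_date):
        emit(
            ERROR, "R9", None,
            f"file-date {p.file_date!r} is not an ISO 8601 YYYY-MM-DD date",
        )
    known = set(GVF_PRAGMAS) | set(GFF3_PRAGMAS)
    for keyword, _rest in p.unknown:
        if keyword not in known:
            emit(WARNING, "R11", None, f"unrecognized pragma ##{keyword}")

    seen_ids: set[str] = set()
    for rec in document.records:
        rid = rec.attributes.id
        if rid:
            if rid in seen_ids:
                emit(ERROR, "R1", rec.line, f"duplicate record ID {rid!r}")
            seen_ids.add(rid)
        _validate_record(emit, rec, ontology)

    return emit.report
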