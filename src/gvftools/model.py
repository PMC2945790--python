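"""In-memory data model for GVF documents.

A GVF file is a GFF3 dialect: eight fixed tab-separated columns (seqid,
source, type, start, end, score, strand, phase) followed by a ninth column
of ``Tag=Value`` attributes.  GVF types the third column with Sequence
Ontology *sequence_alteration* terms (SNV, insertion, deletion,
duplication, ...) and defines eleven alteration-specific attribute tags on
top of the GFF3-inherited ones, plus nine file-level ``##`` pragmas.

This module holds the plain containers (:class:`GvfRecord`,
:class:`Attributes`, :class:`PragmaSet`, :class:`GvfDocument`) and the
checked constructor :func:`make_record`.  The containers themselves are
permissive so that a parser can materialize broken input for the validator
to diagnose; :func:`make_record` is the strict path that rejects invalid
field values outright.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from .errors import CoordinateError, GvfError, MandatoryAttributeError

#: The eight fixed GFF3 columns that precede the attribute column.
FIXED_COLUMNS = ("seqid", "source", "type", "start", "end", "score", "strand", "phase")

#: The GVF attribute tags (Table-style grammar): ID is mandatory, the rest
#: optional.  Unrecognized tags round-trip verbatim through ``extra``.
GVF_ATTRIBUTE_TAGS = (
    "ID",
    "Variant_seq",
    "Reference_seq",
    "Variant_reads",
    "Total_reads",
    "Genotype",
    "Variant_freq",
    "Variant_effect",
    "Variant_copy_number",
    "Reference_copy_number",
    "Nomenclature",
)

#: File-level pragmas specific to GVF (beyond the GFF3-inherited ones).
GVF_PRAGMAS = (
    "file-version",
    "file-date",
    "individual-id",
    "source-method",
    "attribute-method",
    "technology-platform",
    "data-source",
    "phenotype-description",
    "ploidy",
)

#: Pragmas inherited from GFF3 that GVF also understands.
GFF3_PRAGMAS = (
    "gff-version",
    "sequence-region",
    "feature-ontology",
    "attribute-ontology",
    "source-ontology",
    "species",
    "genome-build",
)

#: GFF3 reserved attribute tags that are legal without being GVF-specific.
GFF3_ATTRIBUTE_TAGS = frozenset(
    {
        "Name",
        "Alias",
        "Parent",
        "Target",
        "Gap",
        "Derives_from",
        "Note",
        "Dbxref",
        "Ontology_term",
        "Is_circular",
    }
)

#: A Variant_effect attribute value has exactly this many space-separated
#: structural fields: consequence term, allele index, feature type, ID list.
VARIANT_EFFECT_FIELDS = 4

#: Variant_seq tokens longer than this many nucleotides may be written as '~'.
SEQ_ABBREVIATION_THRESHOLD = 50

GENOTYPES = frozenset({"heterozygous", "homozygous", "hemizygous"})
STRANDS = frozenset({"+", "-", ".", "?"})

# Full one-letter IUPAC nucleotide alphabet; '-' marks a deletion allele and
# '~' an abbreviated long sequence.
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")
SEQ_TOKEN_CODES = IUPAC_CODES | {"-", "~"}

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass(frozen=True)
class VariantEffect:
    """One ``Variant_effect`` entry: the consequence of one variant allele
    on the features it overlaps.

    ``effect_term`` is a SO *sequence_variant* term; ``seq_index`` is the
    0-based index of the causative allele in ``Variant_seq``;
    ``feature_type`` is a SO *sequence_feature* term; ``feature_ids`` lists
    the affected feature identifiers (the comma-split fourth field).
    """

    effect_term: str
    seq_index: int
    feature_type: str
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise GvfError("Variant_effect requires at least one feature ID")
        if self.seq_index < 0:
            raise GvfError("Variant_effect index must be non-negative")
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))


@dataclass
class Attributes:
    """Typed view of a GVF record's ninth column.

    ``variant_seq``, ``variant_reads`` and ``variant_freq`` are positionally
    aligned lists (i-th read count / frequency belongs to the i-th allele).
    Unrecognized tags are preserved verbatim, in order, in ``extra``.
    """

    id: str = ""
    variant_seq: list[str] | None = None
    reference_seq: str | None = None
    variant_reads: list[int] | None = None
    total_reads: int | None = None
    genotype: str | None = None
    variant_freq: list[float] | None = None
    variant_effects: list[VariantEffect] = field(default_factory=list)
    variant_copy_number: int | None = None
    reference_copy_number: int | None = None
    nomenclature: str | None = None
    extra: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant_seq is not None:
            self.variant_seq = [s.upper() for s in self.variant_seq]
        if self.reference_seq is not None:
            self.reference_seq = self.reference_seq.upper()


@dataclass
class GvfRecord:
    """One sequence-alteration line.

    Coordinates are 1-based and inclusive on both ends.  An insertion
    (zero reference length) is anchored at the base immediately 5' of the
    insertion point with ``start == end`` and ``reference_seq == '-'``;
    this keeps ``end >= start`` for every record.  The phase column is
    meaningless for variants and always serializes as ``'.'``.
    """

    seqid: str
    source: str
    so_type: str
    start: int
    end: int
    score: float | None = None
    strand: str = "."
    attributes: Attributes = field(default_factory=Attributes)
    line: int | None = field(default=None, compare=False)

    #: GFF3 phase column — always the null marker for variants.
    phase: str = field(default=".", init=False)

    @property
    def is_insertion(self) -> bool:
        """True when the record carries the insertion coordinate signature."""
        return self.start == self.end and self.attributes.reference_seq == "-"

    def interval(self) -> tuple[int, int]:
        """The (start, end) span stabbed when intersecting with features."""
        return self.start, self.end


@dataclass
class PloidyRegion:
    """A ``##ploidy`` region: the ploidy of one reference span."""

    seqid: str
    start: int
    end: int
    ploidy: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"ploidy region {self.seqid}:{self.start}-{self.end} has invalid coordinates"
            )


@dataclass
class PragmaSet:
    """File-level ``##`` metadata.

    ``genome_build`` is mandatory for GVF (every variant position is
    relative to a named reference assembly).  Structured pragmas
    (individual-id, source-method, attribute-method, technology-platform,
    data-source, phenotype-description) are ``Tag = Value`` maps; ploidy is
    either positional regions or tag maps.  Unknown pragma keywords are
    preserved verbatim.
    """

    gff_version: str = "3"
    genome_build: str | None = None
    file_version: str | None = None
    file_date: str | None = None
    individual_id: dict[str, str] | None = None
    source_methods: list[dict[str, str]] = field(default_factory=list)
    attribute_methods: list[dict[str, str]] = field(default_factory=list)
    technology_platforms: list[dict[str, str]] = field(default_factory=list)
    data_sources: list[dict[str, str]] = field(default_factory=list)
    phenotype_descriptions: list[dict[str, str]] = field(default_factory=list)
    ploidy_regions: list[PloidyRegion] = field(default_factory=list)
    ploidy_terms: list[dict[str, str]] = field(default_factory=list)
    species: str | None = None
    sequence_regions: list[tuple[str, int, int]] = field(default_factory=list)
    feature_ontology: list[str] = field(default_factory=list)
    unknown: list[tuple[str, str]] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)


@dataclass
class GvfDocument:
    """A parsed GVF file: pragmas plus an ordered list of records."""

    pragmas: PragmaSet = field(default_factory=PragmaSet)
    records: list[GvfRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[GvfRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def record_ids(self) -> list[str]:
        return [r.attributes.id for r in self.records]


def make_record(
    seqid: str,
    source: str,
    so_type: str,
    start: int,
    end: int,
    strand: str = ".",
    attributes: Attributes | dict | None = None,
    score: float | None = None,
) -> GvfRecord:
    """Build a :class:`GvfRecord`, rejecting invalid input outright.

    This is the strict constructor: it refuses (rather than repairs)
    records that violate the model invariants.  ``attributes`` may be an
    :class:`Attributes` or a plain dict of Attributes field names.

    Raises
    ------
    MandatoryAttributeError
        if the ID attribute is missing or empty.
    CoordinateError
        if ``start < 1`` or ``end < start``.
    GvfError
        for a strand or genotype outside its enumeration, a frequency
        outside [0, 1], or misaligned allele-indexed lists.
    """
    if isinstance(attributes, dict):
        attributes = Attributes(**attributes)
    elif attributes is None:
        attributes = Attributes()
    if not attributes.id:
        raise MandatoryAttributeError("the ID attribute is mandatory in GVF")
    if start < 1:
        raise CoordinateError(f"start must be >= 1, got {start}")
    if end < start:
        raise CoordinateError(f"end ({end}) < start ({start})")
    if strand not in STRANDS:
        raise GvfError(f"strand must be one of {sorted(STRANDS)}, got {strand!r}")
    if attributes.genotype is not None and attributes.genotype not in GENOTYPES:
        raise GvfError(
            f"genotype must be one of {sorted(GENOTYPES)}, got {attributes.genotype!r}"
        )
    a = attributes
    if a.variant_seq is not None:
        for lst, tag in ((a.variant_reads, "Variant_reads"), (a.variant_freq, "Variant_freq")):
            if lst is not None and len(lst) != len(a.variant_seq):
                raise GvfError(
                    f"{tag} has {len(lst)} values but Variant_seq has {len(a.variant_seq)}"
                )
        for eff in a.variant_effects:
            if eff.seq_index >= len(a.variant_seq):
                raise GvfError(
                    f"Variant_effect index {eff.seq_index} out of range for "
                    f"{len(a.variant_seq)} variant sequence(s)"
                )
    if a.variant_freq is not None and any(not 0.0 <= f <= 1.0 for f in a.variant_freq):
        raise GvfError("Variant_freq values must lie in [0, 1]")
    return GvfRecord(
        seqid=seqid,
        source=source,
        so_type=so_type,
        start=start,
        end=end,
        score=score,
        strand=strand,
        attributes=attributes,
    )


def genotype_consistency(attributes: Attributes) -> bool:
    """Check that the declared genotype agrees with the allele lists.

    homozygous requires exactly one distinct variant sequence;
    heterozygous requires at least two distinct sequences among the variant
    alleles and the reference; hemizygous requires exactly one variant
    sequence.  Vacuously true when genotype or Variant_seq is absent, or
    when the genotype value is outside the known enumeration (that is rule
    R7's business, not this check's).
    """
    a = attributes
    if a.genotype is None or a.variant_seq is None:
        return True
    distinct_variant = set(a.variant_seq)
    if a.genotype == "homozygous":
        return len(distinct_variant) == 1
    if a.genotype == "hemizygous":
        return len(a.variant_seq) == 1
    if a.genotype == "heterozygous":
        observed = set(distinct_variant)
        if a.reference_seq is not None:
            observed.add(a.reference_seq)
        return len(observed) >= 2
    return True


def is_iso_date(value: str) -> bool:
    """True iff *value* is a calendar-valid ISO 8601 YYYY-MM-DD date."""
    if not _DATE_RE.match(value):
        return False
    from datetime import date

    try:
        date.fromisoformat(value)
    except ValueError:
        return False
    return True
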