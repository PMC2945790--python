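# Methods

This note records how gvftools models the Genome Variation Format, the
design decisions taken where the format description leaves room, and
what the synthetic-data tests do and do not demonstrate.

## The format model

A GVF document is a pair (pragmas, records).  Records keep GFF3's eight
fixed columns; coordinates are 1-based and inclusive on both ends.  The
phase column is CDS-specific in GFF3 and meaningless for variants, so it
is always emitted as `.`, and a missing score serializes as `.`.

**Insertion convention.**  The format does not pin down how a
zero-reference-length event is placed on the reference.  We anchor an
insertion at the base immediately 5' of the insertion point with
`start == end` and `Reference_seq = '-'`; the pair (start == end,
reference `-`) is the *insertion signature* recognized by the validator,
the annotator and the VCF converter.  This keeps `end >= start` an
unconditional invariant and makes VCF round trips exact.

**Case and alphabet.**  Sequence tokens are upper-cased on ingest and
compared case-insensitively (providers differ).  The full one-letter
IUPAC nucleotide alphabet is accepted; ambiguity codes outside
A/C/G/T/N raise a warning rather than an error, and characters outside
IUPAC ∪ {`-`, `~`} are errors (rule R12).  `-` marks a deletion allele
and `~` an abbreviated long sequence; both are semantic tokens and are
never percent-encoded.

**Extensibility.**  Unrecognized attribute tags and pragma keywords are
preserved verbatim, in order, and round-trip unchanged — extensibility
is the format's core virtue, so the parser must not destroy what it does
not understand.  Unknown keywords draw a warning (R11); GFF3-inherited
tags (`Name`, `Alias`, `Dbxref`, ...) and pragmas do not.

**Grammar ambiguities resolved.**  (1) `Tag = Value` spacing: examples
write spaces in pragmas but none in column 9; the parser tolerates
optional spaces around `=` (and after commas) everywhere, while the
writer emits single spaces in pragmas and none in column 9.  (2) The
individual-id pragma's documented tag list omits `Ethnicity`, yet usage
includes it; the pragma grammar therefore accepts arbitrary tags and
flags none.  (3) The ploidy pragma appears both positionally
(`##ploidy chr22 1 49691432 diploid`) and as a tag map; both are parsed
and both serialize, positional form preferred on output.  (4) Multiple
`Variant_effect` entries may arrive either as repeated tags or packed in
one comma-separated value (a new entry is recognized by its four
space-delimited fields); the writer always emits repeated tags, which is
unambiguous.

## Serialization and round-trip identity

Output is deterministic: pragmas in canonical order (gff-version,
genome-build, then the rest; repeated pragmas in ingest order), records
in document order, attributes in canonical tag order with extras
trailing in ingest order.  Reserved characters (tab, newline, `;`, `=`,
`,`, `%`, `&`) are percent-encoded inside attribute values.  For every
well-formed document `parse(serialize(doc)) == doc`; the only lossy mode
is explicit: with `abbreviate_long_seqs` enabled, `Variant_seq` tokens
longer than 50 nt are written as `~` (the threshold is the format's
stated abbreviation rule and is exposed as a constant).  Scores and
frequencies are written with `repr`-shortest float formatting so they
survive the round trip bit-exactly.

## Validation

Thirteen rules, all emitted as ordered, line-tagged diagnostics in a
single pass (memory bounded by the ID set, not file size).  Severity
policy: absence of an optional tag is never diagnosed; malformation of a
present tag always is.  Two checks are warnings because the format text
never states the arithmetic: genotype-vs-allele-count consistency (R10:
homozygous ⇒ one distinct variant sequence, heterozygous ⇒ at least two
distinct among variant and reference, hemizygous ⇒ exactly one variant
sequence; a genotype outside the enumeration is R7's business and makes
R10 vacuous) and `Total_reads >= max(Variant_reads)` (R13).  Obsolete
ontology terms warn rather than fail.  Checking `Reference_seq` against
an actual reference genome requires a FASTA the file does not carry and
is out of scope.

## Ontology engine

Branch membership is an `is_a` taxonomy, so only `is_a` edges are
traversed; `part_of`/`derives_from` are ignored for typing.  OBO stanzas
are read with obonet; the wrapped graph memoizes the reflexive-transitive
closure per term, rejects cycles and dangling `is_a` targets at load
time, and resolves terms by accession (case-sensitive) or primary name
(case-insensitive).  The bundled file
`so_subset_synthetic.obo` is a hand-curated ~45-term subgraph covering
the three branches used by GVF (sequence_alteration, sequence_feature,
sequence_variant); it is synthetic in the sense that it tracks no
particular SO release — live SO term counts drift, so the full ontology
is accepted as optional input but never required.

## Converters

VCF sites map to GVF by shared-prefix trimming only; there is no
left-alignment or normalization against the reference (no normalization
rule is part of the format).  Type inference is deliberately coarse —
SNV, insertion, deletion, indel — since anything finer (e.g. transition)
would be guessing.  Multi-allelic sites become one record with a
multi-valued `Variant_seq`, matching the format's comma-list style.  GT
maps 0/1-style heterozygous, 1/1 homozygous, single-call hemizygous;
genotype is left unset when a provider file carries no call.  VCF indels
require the anchor base 5' of the event, which trimmed GVF records no
longer carry, so `gvf_to_vcf` takes an optional reference mapping
(dict of sequences, or an indexed FASTA via `FastaReference`); without
it, pure insertion/deletion records are skipped and counted.  Every
conversion reports (input, converted, skipped) so record conservation is
checkable.

## Annotator

Features are indexed per seqid in an interval tree (intervaltree uses
half-open intervals; the inclusive end is widened by one on insert and
queries).  Overlap is symmetric 1-based inclusive
(`s1 <= e2 and s2 <= e1`); insertions stab at their 5' anchor base;
strand is ignored.  Query results are sorted by (start, end, id) so
annotation output is deterministic.  One `Variant_effect` entry is
emitted per (consequence term, allele index, feature type) with feature
IDs merged into its comma-list; entries of mixed feature types are never
merged.  Annotation is additive and idempotent.  Codon-level consequence
calling (missense vs. synonymous, frameshifts) needs transcript
translation and is not computed; the effect map lets a pipeline supply a
finer consequence term per feature type, validated against the
sequence_variant branch.

## Synthetic data

The generator emulates the *structure* of a single-individual
re-sequencing variant file; its defaults are: alteration mix
SNV : insertion : deletion : duplication = 60 : 15 : 15 : 10 (SNV-heavy,
as in real call sets); 25% of SNVs multi-allelic; geometric indel
lengths with mean 3 nt; one insertion token in 200 longer than 50 nt to
exercise the abbreviation rule; attribute densities of 80% genotype,
70% read counts, 40% frequencies, 50% scores; four seqids with ploidy
pragmas (haploid chrX, hemizygous calls there); coordinates uniform on a
1 Mb region, sorted per seqid, IDs `seqid:source:type:start` and unique.
The first generated record always carries the full attribute complement
so that every attribute-level rule has material to act on.  All draws go
through `random.Random(seed)` using integer `randrange` only, so output
is byte-identical across platforms.

What it does **not** model: allele-frequency spectra, linkage, mutation
spectra (hence the unrealistic ts/tv ≈ 0.5 of uniform draws), error
profiles, or feature hierarchies in the companion GFF3.  Passing tests
therefore demonstrate grammar, rule-set and conversion correctness —
not performance on biologically realistic distributions.

`break_document` is the generator's adjoint: it minimally mutates a
valid document so that exactly one named rule (R1–R12) fires, refusing
when the document carries nothing the rule could act on.  Mutations are
chosen to keep every other rule silent (e.g. the read-alignment break
appends a zero count so the read-total warning cannot co-fire).

## Problem sizes and numerical choices

The test suite and the acceptance script use: 1,000 seeded documents of
10 records for round-trip identity; 100 variants × 100 features against
the all-pairs annotation oracle; every term pair of the bundled ontology
(~2,100 pairs) against an adjacency-matrix closure computed by repeated
squaring; 20-record VCF round trips; and 12 rules × 20 seeds for
validator completeness — sizes at which the whole suite runs in a few
seconds while each comparison is exhaustive rather than sampled.  All
comparisons are exact (string or structural equality); no floating-point
tolerances are needed because numbers round-trip through shortest-repr
formatting.

## Known limitations

Single-source records only (no multi-sample FORMAT blocks or phased
genotypes); `##FASTA` trailers rejected rather than parsed; no tabix
indexing or output sorting; HGVS strings carried opaquely, not
validated; PATO/HPO references pass through as free text; the historical
per-provider dialects of the public 10Gen files are represented only by
the generic tabular converter plus the bundled catalogue.
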