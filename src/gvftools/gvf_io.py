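"""Reading and writing GVF text.

A GVF file contains three kinds of lines: ``##`` pragmas (file-wide
metadata), ``#`` comments, and nine-column tab-separated feature lines
whose ninth column holds ``Tag=Value`` attribute pairs.  The parser is
streaming (records are yielded as lines are read) and lenient where the
validator has a rule to diagnose the problem, strict where the text is
structurally unreadable (wrong column count, non-integer coordinates,
broken attribute syntax).

Serialization is deterministic: pragmas in canonical order (gff-version,
genome-build, then the rest), records in document order, attribute tags in
canonical order with unrecognized tags trailing in ingest order.  Reserved
characters inside attribute values are percent-encoded per the GFF3
convention; ``-`` and ``~`` are semantic sequence tokens and never
encoded.  For every well-formed document ``parse(serialize(doc)) == doc``.
"""

from __future__ import annotations

import gzip
import io
import os
import re
from typing import IO, Iterator

from .errors import (
    AttributeParseError,
    ColumnCountError,
    CoordinateError,
    DateFormatError,
    DuplicateTagError,
    GvfError,
    GvfParseError,
    PragmaError,
)
from .model import (
    Attributes,
    GvfDocument,
    GvfRecord,
    PloidyRegion,
    PragmaSet,
    SEQ_ABBREVIATION_THRESHOLD,
    STRANDS,
    VariantEffect,
    is_iso_date,
)

# GFF3 reserved set: structural characters must be percent-encoded inside
# attribute values (plus '%' itself and '&').
_RESERVED = "\t\n\r;=%&,"
_ENCODE = {c: f"%{ord(c):02X}" for c in _RESERVED}
_PCT_RE = re.compile(r"%([0-9A-Fa-f]{2})")
_PLOIDY_POSITIONAL_RE = re.compile(r"^(\S+)\s+(\d+)\s+(\d+)\s+(\S+)$")

_STRUCTURED_PRAGMAS = {
    "individual-id": "individual_id",
    "source-method": "source_methods",
    "attribute-method": "attribute_methods",
    "technology-platform": "technology_platforms",
    "data-source": "data_sources",
    "phenotype-description": "phenotype_descriptions",
}


def percent_encode(value: str) -> str:
    """Encode GFF3-reserved characters in an attribute value."""
    if not any(c in _ENCODE for c in value):
        return value
    return "".join(_ENCODE.get(c, c) for c in value)


def percent_decode(value: str) -> str:
    """Decode %XX escapes in an attribute value."""
    return _PCT_RE.sub(lambda m: chr(int(m.group(1), 16)), value)


# ---------------------------------------------------------------------------
# attribute parsing
# ---------------------------------------------------------------------------

def _split_values(raw: str) -> list[str]:
    """Comma-split a raw attribute value, tolerating space after commas."""
    return [percent_decode(v.strip()) for v in raw.split(",")]


def _parse_variant_effects(raw: str, line: int | None) -> list[VariantEffect]:
    """Parse one Variant_effect value into one or more four-field entries.

    A single value may carry several entries separated by commas (each new
    entry recognizable by its four space-delimited fields); lone
    comma-separated tokens extend the previous entry's feature-ID list.
    """
    effects: list[VariantEffect] = []
    current: list | None = None  # [term, idx, ftype, [ids]]
    for segment in raw.split(","):
        toks = [percent_decode(t) for t in segment.split()]
        if len(toks) == 4:
            if current is not None:
                effects.append(VariantEffect(*current[:3], tuple(current[3])))
            try:
                idx = int(toks[1])
            except ValueError:
                raise AttributeParseError(
                    f"Variant_effect index is not an integer: {toks[1]!r}", line
                ) from None
            current = [toks[0], idx, toks[2], [toks[3]]]
        elif len(toks) == 1 and current is not None:
            current[3].append(toks[0])
        else:
            raise AttributeParseError(
                "Variant_effect must be four space-delimited fields "
                f"(got {segment.strip()!r})",
                line,
            )
    if current is not None:
        effects.append(VariantEffect(*current[:3], tuple(current[3])))
    return effects


def _int_values(raw: str, tag: str, line: int | None) -> list[int]:
    try:
        return [int(v) for v in _split_values(raw)]
    except ValueError:
        raise AttributeParseError(f"non-integer value for {tag}: {raw!r}", line) from None


def parse_attributes(column9: str, line: int | None = None) -> Attributes:
    """Parse a column-9 attribute string into an :class:`Attributes`.

    Tag-value pairs are ';'-separated, tags split from values on the first
    '=' (spaces around '=' tolerated), multi-values comma-split and
    percent-decoded.  Recognized GVF tags are typed; everything else is
    preserved verbatim in ``extra``.
    """
    attrs = Attributes()
    seen: set[str] = set()
    for part in column9.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise AttributeParseError(f"attribute without '=': {part!r}", line)
        tag, raw = part.split("=", 1)
        tag, raw = tag.strip(), raw.strip()
        if tag in seen and tag != "Variant_effect":
            raise DuplicateTagError(f"duplicate attribute tag {tag!r}", line)
        seen.add(tag)
        if tag == "ID":
            attrs.id = percent_decode(raw)
        elif tag == "Variant_seq":
            attrs.variant_seq = [v.upper() for v in _split_values(raw)]
        elif tag == "Reference_seq":
            attrs.reference_seq = percent_decode(raw).upper()
        elif tag == "Variant_reads":
            attrs.variant_reads = _int_values(raw, tag, line)
        elif tag == "Total_reads":
            attrs.total_reads = _int_values(raw, tag, line)[0]
        elif tag == "Genotype":
            attrs.genotype = percent_decode(raw).lower()
        elif tag == "Variant_freq":
            try:
                attrs.variant_freq = [float(v) for v in _split_values(raw)]
            except ValueError:
                raise AttributeParseError(
                    f"non-numeric value for Variant_freq: {raw!r}", line
                ) from None
        elif tag == "Variant_effect":
            attrs.variant_effects.extend(_parse_variant_effects(raw, line))
        elif tag == "Variant_copy_number":
            attrs.variant_copy_number = _int_values(raw, tag, line)[0]
        elif tag == "Reference_copy_number":
            attrs.reference_copy_number = _int_values(raw, tag, line)[0]
        elif tag == "Nomenclature":
            attrs.nomenclature = percent_decode(raw)
        else:
            values = _split_values(raw)
            if tag in attrs.extra:
                attrs.extra[tag].extend(values)
            else:
                attrs.extra[tag] = values
    return attrs


# ---------------------------------------------------------------------------
# pragma parsing
# ---------------------------------------------------------------------------

def _tag_map(raw: str, keyword: str, line: int | None, strict: bool) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in raw.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            if strict:
                raise PragmaError(f"##{keyword}: entry without '=': {part!r}", line)
            continue
        tag, value = part.split("=", 1)
        out[tag.strip()] = value.strip()
    return out


def parse_pragma(
    line_text: str, line: int | None = None, strict: bool = True
) -> tuple[str, object]:
    """Parse one ``##`` pragma line into ``(keyword, parsed_value)``.

    Structured pragmas become ``Tag = Value`` maps; ploidy is parsed in
    positional form (seqid start end term) or tag form; unknown keywords
    are returned verbatim as ``('unknown', (keyword, rest))``.  With
    ``strict`` a malformed file-date raises :class:`DateFormatError`;
    lenient mode (used during document parsing) keeps the raw value so the
    validator can diagnose it.
    """
    body = line_text[2:].strip()
    if not body:
        raise PragmaError("empty pragma line", line)
    keyword, _, rest = body.partition(" ")
    rest = rest.strip()
    if keyword == "gff-version":
        return "gff-version", rest
    if keyword == "genome-build":
        return "genome-build", rest
    if keyword == "species":
        return "species", rest
    if keyword == "file-version":
        return "file-version", rest
    if keyword == "file-date":
        if strict and not is_iso_date(rest):
            raise DateFormatError(
                f"file-date must be ISO 8601 YYYY-MM-DD, got {rest!r}", line
            )
        return "file-date", rest
    if keyword == "sequence-region":
        toks = rest.split()
        if len(toks) != 3 or not toks[1].isdigit() or not toks[2].isdigit():
            if strict:
                raise PragmaError(f"malformed sequence-region: {rest!r}", line)
            return "unknown", (keyword, rest)
        return "sequence-region", (toks[0], int(toks[1]), int(toks[2]))
    if keyword == "feature-ontology":
        return "feature-ontology", rest
    if keyword == "ploidy":
        m = _PLOIDY_POSITIONAL_RE.match(rest)
        if m:
            region = PloidyRegion(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))
            return "ploidy-region", region
        return "ploidy-term", _tag_map(rest, keyword, line, strict)
    if keyword in _STRUCTURED_PRAGMAS:
        return keyword, _tag_map(rest, keyword, line, strict)
    return "unknown", (keyword, rest)


def _apply_pragma(pragmas: PragmaSet, keyword: str, value: object) -> None:
    if keyword == "gff-version":
        pragmas.gff_version = value  # type: ignore[assignment]
    elif keyword == "genome-build":
        pragmas.genome_build = value  # type: ignore[assignment]
    elif keyword == "species":
        pragmas.species = value  # type: ignore[assignment]
    elif keyword == "file-version":
        pragmas.file_version = value  # type: ignore[assignment]
    elif keyword == "file-date":
        pragmas.file_date = value  # type: ignore[assignment]
    elif keyword == "sequence-region":
        pragmas.sequence_regions.append(value)  # type: ignore[arg-type]
    elif keyword == "feature-ontology":
        pragmas.feature_ontology.append(value)  # type: ignore[arg-type]
    elif keyword == "ploidy-region":
        pragmas.ploidy_regions.append(value)  # type: ignore[arg-type]
    elif keyword == "ploidy-term":
        pragmas.ploidy_terms.append(value)  # type: ignore[arg-type]
    elif keyword == "individual-id":
        pragmas.individual_id = value  # type: ignore[assignment]
    elif keyword in _STRUCTURED_PRAGMAS:
        getattr(pragmas, _STRUCTURED_PRAGMAS[keyword]).append(value)
    else:  # unknown
        pragmas.unknown.append(value)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# feature-line parsing
# ---------------------------------------------------------------------------

def parse_feature_line(text: str, line: int | None = None) -> GvfRecord:
    """Parse one nine-column tab-separated feature line."""
    cols = text.split("\t")
    if len(cols) != 9:
        raise ColumnCountError(
            f"expected 9 tab-separated columns, got {len(cols)}", line
        )
    seqid, source, so_type, start_s, end_s, score_s, strand, _phase, col9 = cols
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise CoordinateError(
            f"start/end must be integers, got {start_s!r}/{end_s!r}", line
        ) from None
    if score_s == ".":
        score = None
    else:
        try:
            score = float(score_s)
        except ValueError:
            raise GvfParseError(f"score must be numeric or '.', got {score_s!r}", line) from None
    if strand not in STRANDS:
        raise GvfParseError(f"strand must be one of +, -, ., ?, got {strand!r}", line)
    attrs = Attributes() if col9 in (".", "") else parse_attributes(col9, line)
    return GvfRecord(
        seqid=seqid,
        source=source,
        so_type=so_type,
        start=start,
        end=end,
        score=score,
        strand=strand,
        attributes=attrs,
        line=line,
    )


# ---------------------------------------------------------------------------
# document-level parse
# ---------------------------------------------------------------------------

def _open_text(source: str | os.PathLike | IO) -> tuple[IO[str], bool]:
    """Return a text stream for *source* (path or stream); gzip transparent."""
    if isinstance(source, (str, os.PathLike)):
        fh = open(source, "rb")
        if fh.read(2) == b"\x1f\x8b":
            fh.seek(0)
            return io.TextIOWrapper(gzip.GzipFile(fileobj=fh)), True
        fh.seek(0)
        return io.TextIOWrapper(fh), True
    if isinstance(source, (bytes, str)):
        raise TypeError("pass text via io.StringIO or parse_text()")
    return source, False


def iter_lines(source: str | os.PathLike | IO) -> Iterator[tuple[int, str]]:
    stream, owned = _open_text(source)
    try:
        for n, raw in enumerate(stream, 1):
            yield n, raw.rstrip("\n").rstrip("\r")
    finally:
        if owned:
            stream.close()


def iter_records(source: str | os.PathLike | IO) -> Iterator[GvfRecord]:
    """Stream records from a GVF file in constant memory (pragmas skipped)."""
    for n, text in iter_lines(source):
        if not text.strip() or text.startswith("#"):
            if text.startswith("##FASTA"):
                raise GvfParseError("embedded ##FASTA sections are not supported", n)
            continue
        yield parse_feature_line(text, n)


def parse(source: str | os.PathLike | IO) -> GvfDocument:
    """Parse a GVF file (path, text stream, or gzip path) into a document.

    Line numbers are retained on records for diagnostics.  Problems the
    validator has a rule for (bad file-date, missing ID, out-of-range
    frequencies, ...) are let through; structurally unreadable lines
    raise a :class:`GvfParseError` subclass tagged with the line number.
    """
    doc = GvfDocument()
    for n, text in iter_lines(source):
        if not text.strip():
            continue
        if text.startswith("##FASTA"):
            raise GvfParseError("embedded ##FASTA sections are not supported", n)
        if text == "###":
            doc.pragmas.comments.append(text)
        elif text.startswith("##"):
            keyword, value = parse_pragma(text, n, strict=False)
            _apply_pragma(doc.pragmas, keyword, value)
        elif text.startswith("#"):
            doc.pragmas.comments.append(text)
        else:
            doc.records.append(parse_feature_line(text, n))
    return doc


def parse_text(text: str) -> GvfDocument:
    """Parse GVF from an in-memory string."""
    return parse(io.StringIO(text))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _fmt_number(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() and abs(x) < 1e15 else repr(float(x))


def _check_serializable(record: GvfRecord) -> None:
    a = record.attributes
    problems = []
    if not a.id:
        problems.append("missing mandatory ID")
    if record.start < 1:
        problems.append(f"start {record.start} < 1")
    if record.end < record.start:
        problems.append(f"end {record.end} < start {record.start}")
    if a.variant_seq is not None:
        for lst, tag in ((a.variant_reads, "Variant_reads"), (a.variant_freq, "Variant_freq")):
            if lst is not None and len(lst) != len(a.variant_seq):
                problems.append(f"{tag} not aligned with Variant_seq")
    if problems:
        where = f" (line {record.line})" if record.line else ""
        raise GvfError(
            f"refusing to serialize invalid record {a.id!r}{where}: " + "; ".join(problems)
        )


def _seq_token(token: str, abbreviate: bool) -> str:
    if abbreviate and len(token) > SEQ_ABBREVIATION_THRESHOLD:
        return "~"
    return percent_encode(token)


def format_attributes(attrs: Attributes, abbreviate_long_seqs: bool = False) -> str:
    """Serialize an :class:`Attributes` to canonical column-9 text."""
    parts = [f"ID={percent_encode(attrs.id)}"]
    if attrs.variant_seq is not None:
        parts.append(
            "Variant_seq="
            + ",".join(_seq_token(t, abbreviate_long_seqs) for t in attrs.variant_seq)
        )
    if attrs.reference_seq is not None:
        parts.append("Reference_seq=" + percent_encode(attrs.reference_seq))
    if attrs.variant_reads is not None:
        parts.append("Variant_reads=" + ",".join(str(v) for v in attrs.variant_reads))
    if attrs.total_reads is not None:
        parts.append(f"Total_reads={attrs.total_reads}")
    if attrs.genotype is not None:
        parts.append(f"Genotype={percent_encode(attrs.genotype)}")
    if attrs.variant_freq is not None:
        parts.append("Variant_freq=" + ",".join(_fmt_number(v) for v in attrs.variant_freq))
    for eff in attrs.variant_effects:
        ids = ",".join(percent_encode(i) for i in eff.feature_ids)
        parts.append(
            "Variant_effect="
            f"{percent_encode(eff.effect_term)} {eff.seq_index} "
            f"{percent_encode(eff.feature_type)} {ids}"
        )
    if attrs.variant_copy_number is not None:
        parts.append(f"Variant_copy_number={attrs.variant_copy_number}")
    if attrs.reference_copy_number is not None:
        parts.append(f"Reference_copy_number={attrs.reference_copy_number}")
    if attrs.nomenclature is not None:
        parts.append("Nomenclature=" + percent_encode(attrs.nomenclature))
    for tag, values in attrs.extra.items():
        parts.append(f"{tag}=" + ",".join(percent_encode(v) for v in values))
    return ";".join(parts)


def format_record(record: GvfRecord, abbreviate_long_seqs: bool = False) -> str:
    """Serialize one record to a nine-column line (no trailing newline)."""
    _check_serializable(record)
    score = "." if record.score is None else _fmt_number(record.score)
    return "\t".join(
        (
            record.seqid,
            record.source,
            record.so_type,
            str(record.start),
            str(record.end),
            score,
            record.strand,
            record.phase,
            format_attributes(record.attributes, abbreviate_long_seqs),
        )
    )


def _pragma_lines(p: PragmaSet) -> Iterator[str]:
    def tag_join(m: dict[str, str]) -> str:
        return ";".join(f"{k} = {v}" for k, v in m.items())

    yield f"##gff-version {p.gff_version}".rstrip()
    if p.genome_build is not None:
        yield f"##genome-build {p.genome_build}"
    if p.file_version is not None:
        yield f"##file-version {p.file_version}"
    if p.file_date is not None:
        yield f"##file-date {p.file_date}"
    if p.individual_id is not None:
        yield f"##individual-id {tag_join(p.individual_id)}"
    for keyword, attr in (
        ("source-method", p.source_methods),
        ("attribute-method", p.attribute_methods),
        ("technology-platform", p.technology_platforms),
        ("data-source", p.data_sources),
        ("phenotype-description", p.phenotype_descriptions),
    ):
        for entry in attr:
            yield f"##{keyword} {tag_join(entry)}"
    for r in p.ploidy_regions:
        yield f"##ploidy {r.seqid} {r.start} {r.end} {r.ploidy}"
    for entry in p.ploidy_terms:
        yield f"##ploidy {tag_join(entry)}"
    if p.species is not None:
        yield f"##species {p.species}"
    for seqid, start, end in p.sequence_regions:
        yield f"##sequence-region {seqid} {start} {end}"
    for fo in p.feature_ontology:
        yield f"##feature-ontology {fo}"
    for keyword, rest in p.unknown:
        yield f"##{keyword} {rest}".rstrip()
    yield from p.comments


def serialize(
    document: GvfDocument,
    stream: IO[str] | None = None,
    abbreviate_long_seqs: bool = False,
) -> str | None:
    """Write a document as GVF text.

    With ``abbreviate_long_seqs``, Variant_seq tokens longer than 50
    nucleotides are emitted as ``~`` (lossy; off by default so that
    serialization round-trips).  Returns the text when *stream* is None.
    """
    out = stream or io.StringIO()
    for line in _pragma_lines(document.pragmas):
        out.write(line + "\n")
    for record in document.records:
        out.write(format_record(record, abbreviate_long_seqs) + "\n")
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None
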