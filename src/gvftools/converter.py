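"""Conversion between VCF / tabular variant calls and GVF.

The mapping (VCF -> GVF): CHROM becomes the seqid, POS/REF/ALT become
1-based inclusive coordinates plus ``Reference_seq``/``Variant_seq`` after
shared-prefix trimming, QUAL becomes the score, the sample GT call becomes
the ``Genotype`` enumeration, AD/DP become ``Variant_reads``/
``Total_reads``, and the VCF ID is preserved as a Dbxref/Alias attribute.
The alteration type is inferred coarsely: same-length single-base
substitution -> SNV, emptied ALT -> deletion, emptied REF -> insertion,
anything else -> indel.  An insertion is anchored at the reference base
immediately 5' of the event with ``start == end`` and ``Reference_seq``
``'-'``.

The reverse direction inverts that mapping.  VCF requires an anchor base
for pure insertion/deletion alleles which trimmed GVF records no longer
carry, so ``gvf_to_vcf`` takes an optional *reference* (any mapping of
seqid to sliceable sequence, e.g. a dict of strings or a pyfaidx Fasta);
without one, such records are skipped with a warning.

Only the shared prefix is trimmed — there is no left-alignment against
the reference.  Multi-allelic sites become one GVF record with a
multi-valued ``Variant_seq``, not several records.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pysam

from .errors import ConversionError
from .model import Attributes, GvfDocument, GvfRecord, PragmaSet

_SUPPORTED_TYPES = ("SNV", "insertion", "deletion", "indel")

_GENOTYPE_ALIASES = {
    "het": "heterozygous",
    "hom": "homozygous",
    "hemi": "hemizygous",
    "heterozygous": "heterozygous",
    "homozygous": "homozygous",
    "hemizygous": "hemizygous",
}


@dataclass
class ConversionResult:
    """Outcome of a conversion: payload plus conservation accounting."""

    document: GvfDocument | None = None
    text: str | None = None
    n_input: int = 0
    n_converted: int = 0
    n_skipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def _skip(self, message: str) -> None:
        self.n_skipped += 1
        self.warnings.append(message)


@dataclass
class TableDialect:
    """Column layout of a provider's tabular variant file.

    ``columns`` maps 0-based column index to a role among ``seqid``,
    ``pos``, ``ref``, ``alt``, ``reads``, ``total_reads``, ``genotype``.
    ``delimiter`` of None splits on any whitespace.
    """

    columns: dict[int, str]
    delimiter: str | None = "\t"
    source: str = "table"

    def __post_init__(self) -> None:
        roles = set(self.columns.values())
        for needed in ("seqid", "pos", "ref", "alt"):
            if needed not in roles:
                raise ConversionError(f"dialect is missing the {needed!r} column role")


# ---------------------------------------------------------------------------
# allele arithmetic shared by both input paths
# ---------------------------------------------------------------------------

def trim_shared_prefix(ref: str, alts: tuple[str, ...]) -> tuple[int, str, tuple[str, ...]]:
    """Drop the prefix common to REF and every ALT; return (n_trimmed, ref, alts)."""
    k = 0
    seqs = (ref, *alts)
    limit = min(len(s) for s in seqs)
    while k < limit and len({s[k] for s in seqs}) == 1:
        k += 1
    return k, ref[k:], tuple(a[k:] for a in alts)


def classify_alteration(ref_t: str, alts_t: tuple[str, ...]) -> str:
    """Infer the coarse SO alteration type from trimmed alleles."""
    if ref_t == "":
        return "insertion"
    if all(a == "" for a in alts_t):
        return "deletion"
    if len(ref_t) == 1 and all(len(a) == 1 for a in alts_t):
        return "SNV"
    return "indel"


def alleles_to_gvf(
    chrom: str, pos: int, ref: str, alts: tuple[str, ...]
) -> tuple[str, int, int, str, list[str]]:
    """Map a VCF-style site to (so_type, start, end, reference_seq, variant_seq).

    *pos* is the 1-based position of the first REF base.  Raises
    :class:`ConversionError` for a degenerate site (an ALT equal to REF).
    """
    ref = ref.upper()
    alts = tuple(a.upper() for a in alts)
    if any(a == ref for a in alts):
        raise ConversionError(f"{chrom}:{pos}: ALT identical to REF ({ref})")
    k, ref_t, alts_t = trim_shared_prefix(ref, alts)
    so_type = classify_alteration(ref_t, alts_t)
    if ref_t == "":
        # insertion: anchor on the base 5' of the insertion point
        start = end = pos + k - 1
        reference_seq = "-"
    else:
        start = pos + k
        end = start + len(ref_t) - 1
        reference_seq = ref_t
    variant_seq = [a if a else "-" for a in alts_t]
    return so_type, start, end, reference_seq, variant_seq


def _genotype_from_calls(calls: tuple[int | None, ...]) -> str | None:
    called = [c for c in calls if c is not None]
    if not called or all(c == 0 for c in called):
        return None
    if len(called) == 1:
        return "hemizygous"
    return "homozygous" if len(set(called)) == 1 else "heterozygous"


def _apply_provenance(pragmas: PragmaSet, config: Mapping | None) -> None:
    if not config:
        return
    if "genome_build" in config:
        pragmas.genome_build = config["genome_build"]
    if "individual_id" in config:
        pragmas.individual_id = dict(config["individual_id"])
    for key, attr in (
        ("source_method", "source_methods"),
        ("attribute_method", "attribute_methods"),
        ("technology_platform", "technology_platforms"),
        ("data_source", "data_sources"),
    ):
        entries = config.get(key)
        if entries is None:
            continue
        if isinstance(entries, Mapping):
            entries = [entries]
        getattr(pragmas, attr).extend(dict(e) for e in entries)


def _unique_id(base: str, used: set[str]) -> str:
    rid, n = base, 1
    while rid in used:
        n += 1
        rid = f"{base}:{n}"
    used.add(rid)
    return rid


# ---------------------------------------------------------------------------
# VCF -> GVF
# ---------------------------------------------------------------------------

def _vcf_path(source: str | os.PathLike | IO[str]) -> tuple[str, str | None]:
    """Materialize a file-like VCF source to a path pysam can open."""
    if isinstance(source, (str, os.PathLike)):
        return os.fspath(source), None
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".vcf", delete=False, encoding="utf-8"
    )
    tmp.write(source.read())
    tmp.close()
    return tmp.name, tmp.name


def vcf_to_gvf(
    vcf: str | os.PathLike | IO[str],
    provenance: Mapping | None = None,
    sample: str | None = None,
    source_label: str | None = None,
) -> ConversionResult:
    """Convert a VCF 4.x file (single-sample or site-only) to GVF.

    *provenance* may supply ``genome_build``, ``individual_id``, and
    ``source_method`` / ``technology_platform`` / ``data_source`` pragma
    maps.  A multi-sample VCF is refused unless *sample* names one of its
    samples.  Symbolic ALTs (``<DEL>``, breakends) and degenerate sites
    are skipped with a warning, and the skip count is reported.
    """
    path, cleanup = _vcf_path(vcf)
    result = ConversionResult(document=GvfDocument())
    provenance = dict(provenance or {})
    source = source_label or provenance.get("source", "gvftools")
    pragmas = result.document.pragmas
    pragmas.genome_build = "unknown unknown"
    _apply_provenance(pragmas, provenance)
    used_ids: set[str] = set()
    try:
        with pysam.VariantFile(path) as vf:
            samples = list(vf.header.samples)
            if sample is None and len(samples) > 1:
                raise ConversionError(
                    f"multi-sample VCF ({len(samples)} samples): name one with sample="
                )
            if sample is not None and sample not in samples:
                raise ConversionError(f"sample {sample!r} not in VCF header")
            if sample is None and samples:
                sample = samples[0]
            for vrec in vf:
                result.n_input += 1
                rec = _convert_vcf_record(vrec, sample, source, used_ids, result)
                if rec is not None:
                    result.document.records.append(rec)
                    result.n_converted += 1
    finally:
        if cleanup:
            os.unlink(cleanup)
    return result


def _convert_vcf_record(
    vrec, sample: str | None, source: str, used_ids: set[str], result: ConversionResult
) -> GvfRecord | None:
    where = f"{vrec.chrom}:{vrec.pos}"
    alts = vrec.alts
    if not alts:
        result._skip(f"{where}: no alternate allele")
        return None
    if any(a is None or a.startswith("<") or any(c in a for c in "[]") for a in alts):
        result._skip(f"{where}: symbolic or breakend ALT not supported")
        return None
    try:
        so_type, start, end, reference_seq, variant_seq = alleles_to_gvf(
            vrec.chrom, vrec.pos, vrec.ref, tuple(alts)
        )
    except ConversionError as exc:
        result._skip(str(exc))
        return None

    attrs = Attributes(
        id=_unique_id(f"{vrec.chrom}:{source}:{so_type}:{start}", used_ids),
        variant_seq=variant_seq,
        reference_seq=reference_seq,
    )
    if vrec.id and vrec.id != ".":
        if vrec.id.startswith("rs"):
            attrs.extra["Dbxref"] = [f"dbSNP:{vrec.id}"]
        else:
            attrs.extra["Alias"] = [vrec.id]
    if sample is not None:
        call = vrec.samples[sample]
        gt = call.get("GT")
        if gt is not None:
            attrs.genotype = _genotype_from_calls(tuple(gt))
        ad = call.get("AD")
        if ad is not None and len(ad) == len(alts) + 1 and all(
            x is not None for x in ad[1:]
        ):
            attrs.variant_reads = [int(x) for x in ad[1:]]
        dp = call.get("DP")
        if dp is not None:
            attrs.total_reads = int(dp)
    return GvfRecord(
        seqid=vrec.chrom,
        source=source,
        so_type=so_type,
        start=start,
        end=end,
        score=float(vrec.qual) if vrec.qual is not None else None,
        strand="+",
        attributes=attrs,
    )


# ---------------------------------------------------------------------------
# GVF -> VCF
# ---------------------------------------------------------------------------

def _gvf_record_to_site(
    rec: GvfRecord, reference: Mapping | None
) -> tuple[int, str, list[str]] | str:
    """Reconstruct (POS, REF, ALTs); returns a skip reason on failure."""
    a = rec.attributes
    if a.reference_seq is None or a.variant_seq is None:
        return "needs both Reference_seq and Variant_seq"
    if any(t == "~" for t in a.variant_seq):
        return "abbreviated ('~') variant sequence"
    needs_anchor = rec.is_insertion or "-" in a.variant_seq
    if not needs_anchor:
        return rec.start, a.reference_seq, list(a.variant_seq)
    if reference is None or rec.seqid not in reference:
        return "insertion/deletion allele needs a reference anchor base"
    if rec.is_insertion:
        anchor_pos = rec.start  # base 5' of the insertion point
        anchor = str(reference[rec.seqid][anchor_pos - 1 : anchor_pos]).upper()
        return anchor_pos, anchor, [anchor + t for t in a.variant_seq]
    anchor_pos = rec.start - 1
    if anchor_pos < 1:
        return "deletion at position 1 has no 5' anchor base"
    anchor = str(reference[rec.seqid][anchor_pos - 1 : anchor_pos]).upper()
    ref = anchor + a.reference_seq
    alts = [anchor if t == "-" else anchor + t for t in a.variant_seq]
    return anchor_pos, ref, alts


def _gt_tuple(genotype: str | None, n_alts: int) -> tuple[int | None, ...]:
    if genotype == "hemizygous":
        return (1,)
    if genotype == "homozygous":
        return (1, 1)
    if genotype == "heterozygous":
        return (1, 2) if n_alts >= 2 else (0, 1)
    return (None,)


def gvf_to_vcf(
    document: GvfDocument,
    stream: IO[str] | None = None,
    reference: Mapping | None = None,
) -> ConversionResult:
    """Convert a GVF document to a minimal single-sample VCF.

    Inverse of :func:`vcf_to_gvf` on its image.  Records without a
    concrete reconstructable site (abbreviated sequences, indels without a
    *reference* to supply the VCF anchor base) are skipped with a warning.
    The VCF text is returned in ``result.text`` and also written to
    *stream* when given.
    """
    result = ConversionResult()
    sites: list[tuple[GvfRecord, int, str, list[str]]] = []
    contigs: list[str] = []
    any_sample = False
    for rec in document.records:
        result.n_input += 1
        site = _gvf_record_to_site(rec, reference)
        if isinstance(site, str):
            result._skip(f"{rec.attributes.id or rec.seqid}: {site}")
            continue
        sites.append((rec, *site))
        if rec.seqid not in contigs:
            contigs.append(rec.seqid)
        if rec.attributes.genotype or rec.attributes.variant_reads is not None:
            any_sample = True

    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    if any_sample:
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("AD", "R", "Integer", "Allelic depths")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.add_sample("SAMPLE")

    tmp = tempfile.NamedTemporaryFile(suffix=".vcf", delete=False)
    tmp.close()
    try:
        with pysam.VariantFile(tmp.name, "w", header=header) as out:
            for rec, pos, ref, alts in sites:
                a = rec.attributes
                vrec = out.new_record(
                    contig=rec.seqid,
                    start=pos - 1,
                    alleles=(ref, *alts),
                    qual=rec.score,
                )
                dbxref = a.extra.get("Dbxref", [])
                alias = a.extra.get("Alias", [])
                rsids = [x.split(":", 1)[1] for x in dbxref if x.startswith("dbSNP:")]
                if rsids:
                    vrec.id = rsids[0]
                elif alias:
                    vrec.id = alias[0]
                if any_sample:
                    call = vrec.samples["SAMPLE"]
                    call["GT"] = _gt_tuple(a.genotype, len(alts))
                    if a.variant_reads is not None and len(a.variant_reads) == len(alts):
                        call["AD"] = (None, *a.variant_reads)
                    if a.total_reads is not None:
                        call["DP"] = a.total_reads
                out.write(vrec)
                result.n_converted += 1
        with open(tmp.name, encoding="utf-8") as fh:
            result.text = fh.read()
    finally:
        os.unlink(tmp.name)
    if stream is not None:
        stream.write(result.text)
    return result


class FastaReference:
    """Adapt an indexed FASTA (via pysam) to the mapping-of-sliceables
    interface :func:`gvf_to_vcf` expects for its anchor lookups."""

    class _Contig:
        def __init__(self, fasta: pysam.FastaFile, name: str):
            self._fasta, self._name = fasta, name

        def __getitem__(self, key: slice) -> str:
            return self._fasta.fetch(self._name, key.start, key.stop)

    def __init__(self, path: str | os.PathLike):
        self._fasta = pysam.FastaFile(os.fspath(path))

    def __contains__(self, name: str) -> bool:
        return name in self._fasta.references

    def __getitem__(self, name: str) -> "FastaReference._Contig":
        return self._Contig(self._fasta, name)

    def close(self) -> None:
        self._fasta.close()


# ---------------------------------------------------------------------------
# tabular -> GVF
# ---------------------------------------------------------------------------

def table_to_gvf(
    rows: Iterable[str] | IO[str],
    dialect: TableDialect,
    provenance: Mapping | None = None,
) -> ConversionResult:
    """Convert delimited provider text to GVF using a column-role dialect.

    Applies the same allele arithmetic as :func:`vcf_to_gvf`; record IDs
    are auto-generated as ``seqid:source:type:position``.  Rows shorter
    than the dialect demands produce a row-level warning and are skipped.
    """
    result = ConversionResult(document=GvfDocument())
    pragmas = result.document.pragmas
    pragmas.genome_build = "unknown unknown"
    _apply_provenance(pragmas, provenance)
    need = max(dialect.columns) + 1
    roles = {role: idx for idx, role in dialect.columns.items()}
    used_ids: set[str] = set()
    for n, raw in enumerate(rows, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        result.n_input += 1
        cols = line.split(dialect.delimiter) if dialect.delimiter else line.split()
        if len(cols) < need:
            result._skip(f"row {n}: {len(cols)} column(s), dialect needs {need}")
            continue
        try:
            pos = int(cols[roles["pos"]])
        except ValueError:
            result._skip(f"row {n}: non-integer position {cols[roles['pos']]!r}")
            continue
        seqid = cols[roles["seqid"]]
        ref = cols[roles["ref"]].upper()
        alts = tuple(t.strip().upper() for t in cols[roles["alt"]].split(","))
        try:
            so_type, start, end, reference_seq, variant_seq = alleles_to_gvf(
                seqid, pos, ref, alts
            )
        except ConversionError as exc:
            result._skip(f"row {n}: {exc}")
            continue
        attrs = Attributes(
            id=_unique_id(f"{seqid}:{dialect.source}:{so_type}:{start}", used_ids),
            variant_seq=variant_seq,
            reference_seq=reference_seq,
        )
        if "reads" in roles:
            try:
                attrs.variant_reads = [int(v) for v in cols[roles["reads"]].split(",")]
            except ValueError:
                pass
        if "total_reads" in roles:
            try:
                attrs.total_reads = int(cols[roles["total_reads"]])
            except ValueError:
                pass
        if "genotype" in roles:
            attrs.genotype = _GENOTYPE_ALIASES.get(cols[roles["genotype"]].lower())
        result.document.records.append(
            GvfRecord(
                seqid=seqid,
                source=dialect.source,
                so_type=so_type,
                start=start,
                end=end,
                strand="+",
                attributes=attrs,
            )
        )
        result.n_converted += 1
    return result
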