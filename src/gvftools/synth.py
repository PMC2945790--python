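"""Seeded synthetic GVF / GFF3 / VCF generation, plus targeted breakage.

The generator emulates a single-individual re-sequencing variant file:
SNVs dominate, with smaller fractions of short insertions and deletions
and occasional duplications (copy-number records), read-depth and
genotype attributes at realistic densities, and file-level provenance
pragmas.  Structure, not population genetics, is what is modelled —
coordinates are uniform, alleles i.i.d. over A/C/G/T — so these documents
exercise the format grammar and rule set, nothing more.

Every draw goes through ``random.Random(seed)`` with integer arithmetic
(``randrange``), so output is byte-identical across platforms for a fixed
seed, and every generated document passes the validator with zero
diagnostics.  :func:`break_document` is the adjoint tool: it minimally
mutates a valid document so that exactly one named validator rule fires.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field

from .errors import GeneratorError
from .model import (
    Attributes,
    GvfDocument,
    GvfRecord,
    PloidyRegion,
    PragmaSet,
    VariantEffect,
)

_BASES = "ACGT"

#: Validator rules break_document knows how to trigger.
BREAKABLE_RULES = tuple(f"R{i}" for i in range(1, 13))


@dataclass
class Profile:
    """Knobs for the document generator.

    ``type_weights`` are integer proportions of alteration types;
    ``indel_mean_len`` is the mean of the geometric length distribution
    for inserted/deleted sequence; one variant token in
    ``long_token_rate`` exceeds the 50-nt abbreviation threshold.
    """

    type_weights: dict[str, int] = field(
        default_factory=lambda: {
            "SNV": 60,
            "insertion": 15,
            "deletion": 15,
            "duplication": 10,
        }
    )
    seqids: tuple[str, ...] = ("chr1", "chr2", "chr3", "chrX")
    region_length: int = 1_000_000
    indel_mean_len: int = 3
    long_token_rate: int = 200  # 1 in N insertion tokens is > 50 nt
    multiallelic_pct: int = 25  # of SNVs carry two alternate alleles
    p_genotype: int = 80  # percent
    p_reads: int = 70
    p_freq: int = 40
    p_score: int = 50
    p_nomenclature: int = 10
    include_ploidy: bool = True
    source: str = "synth"
    genome_build: str = "NCBI B36"


def _weighted_choice(rng: random.Random, weights: dict[str, int]) -> str:
    total = sum(weights.values())
    r = rng.randrange(total)
    for item, w in weights.items():
        if r < w:
            return item
        r -= w
    raise AssertionError("unreachable")


def _geometric(rng: random.Random, mean: int) -> int:
    """Geometric length >= 1 with the given mean, via integer draws."""
    # success probability 1/mean represented on a 0..mean-1 die
    n = 1
    while rng.randrange(mean) != 0 and n < 200:
        n += 1
    return n


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(_BASES[rng.randrange(4)] for _ in range(length))


def _other_base(rng: random.Random, *exclude: str) -> str:
    while True:
        b = _BASES[rng.randrange(4)]
        if b not in exclude:
            return b


def generate_reference(
    seed: int, seqids: tuple[str, ...] = ("chr1", "chr2"), length: int = 10_000
) -> dict[str, str]:
    """A deterministic random reference genome (dict of seqid -> sequence)."""
    rng = random.Random(seed)
    return {s: _random_seq(rng, length) for s in seqids}


# ---------------------------------------------------------------------------
# GVF document generation
# ---------------------------------------------------------------------------

def _base_pragmas(seed: int, profile: Profile) -> PragmaSet:
    p = PragmaSet(
        gff_version="3",
        genome_build=profile.genome_build,
        file_version="1.0",
        file_date="2010-01-15",
        individual_id={
            "Dbxref": f"synthetic:IND-{seed % 1000:03d}",
            "Gender": "female" if seed % 2 else "male",
        },
    )
    p.source_methods.append(
        {"Source": profile.source, "Type": "SNV", "Comment": "simulated caller"}
    )
    p.technology_platforms.append(
        {
            "Source": profile.source,
            "Type": "SNV",
            "Platform_class": "short read sequencing",
            "Platform_name": "simulated",
        }
    )
    if profile.include_ploidy:
        for seqid in profile.seqids:
            ploidy = "haploid" if seqid in ("chrX", "chrY") else "diploid"
            p.ploidy_regions.append(
                PloidyRegion(seqid, 1, profile.region_length, ploidy)
            )
    return p


def _snv_attrs(rng: random.Random, profile: Profile, force_rich: bool) -> tuple[str, list[str], Attributes]:
    ref = _BASES[rng.randrange(4)]
    multi = force_rich or rng.randrange(100) < profile.multiallelic_pct
    if multi:
        a1 = _other_base(rng, ref)
        a2 = _other_base(rng, ref, a1)
        variant = [a1, a2]
        genotype = "heterozygous"
    else:
        variant = [_other_base(rng, ref)]
        genotype = "homozygous" if rng.randrange(2) else "heterozygous"
    return ref, variant, Attributes(genotype=genotype)


def _indel_seq(rng: random.Random, profile: Profile, allow_long: bool) -> str:
    if allow_long and rng.randrange(profile.long_token_rate) == 0:
        return _random_seq(rng, 51 + rng.randrange(30))
    return _random_seq(rng, _geometric(rng, profile.indel_mean_len))


def _make_record(
    rng: random.Random,
    profile: Profile,
    seqid: str,
    pos: int,
    so_type: str,
    force_rich: bool,
) -> GvfRecord:
    start = end = pos
    attrs = Attributes()
    genotype: str | None = None
    if so_type == "SNV":
        ref, variant, ga = _snv_attrs(rng, profile, force_rich)
        attrs.reference_seq = ref
        attrs.variant_seq = variant
        genotype = ga.genotype
    elif so_type == "deletion":
        d = _geometric(rng, profile.indel_mean_len)
        attrs.reference_seq = _random_seq(rng, d)
        attrs.variant_seq = ["-"]
        end = pos + d - 1
        genotype = "homozygous" if rng.randrange(2) else "heterozygous"
    elif so_type == "insertion":
        attrs.reference_seq = "-"
        attrs.variant_seq = [_indel_seq(rng, profile, allow_long=True)]
        genotype = "homozygous" if rng.randrange(2) else "heterozygous"
    elif so_type == "duplication":
        end = pos + 100 + rng.randrange(900)
        attrs.variant_copy_number = 2 + rng.randrange(6)
        attrs.reference_copy_number = 1
    else:
        raise GeneratorError(f"profile names unknown alteration type {so_type!r}")

    if seqid in ("chrX", "chrY") and attrs.variant_seq is not None:
        genotype = "hemizygous"
        attrs.variant_seq = attrs.variant_seq[:1]

    rich = force_rich
    if attrs.variant_seq is not None:
        n = len(attrs.variant_seq)
        if rich or rng.randrange(100) < profile.p_reads:
            attrs.variant_reads = [5 + rng.randrange(55) for _ in range(n)]
            attrs.total_reads = sum(attrs.variant_reads) + rng.randrange(30)
        if rich or rng.randrange(100) < profile.p_freq:
            attrs.variant_freq = [(1 + rng.randrange(50)) / 100 for _ in range(n)]
        if rich or rng.randrange(100) < profile.p_genotype:
            attrs.genotype = genotype
    score = None
    if rng.randrange(100) < profile.p_score:
        score = float(10 + rng.randrange(90))
    if so_type == "SNV" and rng.randrange(100) < profile.p_nomenclature:
        attrs.nomenclature = (
            f"HGVS: g.{pos}{attrs.reference_seq}>{attrs.variant_seq[0]}"
        )
    attrs.id = ""  # assigned after position sorting
    return GvfRecord(
        seqid=seqid,
        source=profile.source,
        so_type=so_type,
        start=start,
        end=end,
        score=score,
        strand="+",
        attributes=attrs,
    )


def generate_document(
    seed: int, n_records: int = 50, profile: Profile | None = None
) -> GvfDocument:
    """Generate a valid GVF document: deterministic for a fixed seed,
    records sorted by position within each seqid, IDs unique.

    The first record generated (when ``n_records >= 1``) always carries
    the full attribute complement (two alternate alleles, reads,
    frequencies, genotype) so that every attribute-level validator rule
    has material to act on.
    """
    if n_records < 0:
        raise GeneratorError(f"n_records must be non-negative, got {n_records}")
    profile = profile or Profile()
    rng = random.Random(seed)
    doc = GvfDocument(pragmas=_base_pragmas(seed, profile))

    per_seqid: dict[str, list[GvfRecord]] = {s: [] for s in profile.seqids}
    used_pos: dict[str, set[int]] = {s: set() for s in profile.seqids}
    for i in range(n_records):
        force_rich = i == 0
        seqid = profile.seqids[rng.randrange(len(profile.seqids))]
        if force_rich:
            seqid = profile.seqids[0]  # keep the rich anchor off hemizygous seqids
        so_type = "SNV" if force_rich else _weighted_choice(rng, profile.type_weights)
        while True:
            pos = 1 + rng.randrange(profile.region_length - 2000)
            if pos not in used_pos[seqid]:
                used_pos[seqid].add(pos)
                break
        per_seqid[seqid].append(
            _make_record(rng, profile, seqid, pos, so_type, force_rich)
        )

    used_ids: set[str] = set()
    for seqid in profile.seqids:
        for rec in sorted(per_seqid[seqid], key=lambda r: (r.start, r.end)):
            base = f"{rec.seqid}:{rec.source}:{rec.so_type}:{rec.start}"
            rid, n = base, 1
            while rid in used_ids:
                n += 1
                rid = f"{base}:{n}"
            used_ids.add(rid)
            rec.attributes.id = rid
            doc.records.append(rec)
    return doc


# ---------------------------------------------------------------------------
# companion GFF3 and VCF generation
# ---------------------------------------------------------------------------

def generate_gff3(
    seed: int,
    n_features: int = 100,
    seqids: tuple[str, ...] = ("chr1", "chr2", "chr3", "chrX"),
    region_length: int = 1_000_000,
) -> str:
    """A synthetic GFF3 annotation file (gene/mRNA/exon/CDS features)."""
    rng = random.Random(seed)
    types = {"gene": 25, "mRNA": 25, "exon": 30, "CDS": 20}
    lines = ["##gff-version 3"]
    for i in range(n_features):
        seqid = seqids[rng.randrange(len(seqids))]
        ftype = _weighted_choice(rng, types)
        start = 1 + rng.randrange(region_length - 20_000)
        span = {"gene": 10_000, "mRNA": 8_000, "exon": 300, "CDS": 200}[ftype]
        end = start + 1 + rng.randrange(span)
        strand = "+" if rng.randrange(2) else "-"
        fid = f"{ftype}{i:05d}"
        lines.append(
            f"{seqid}\tsynth\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\tID={fid}"
        )
    return "\n".join(lines) + "\n"


def generate_vcf(
    seed: int,
    n_records: int = 20,
    seqids: tuple[str, ...] = ("chr1", "chr2"),
    region_length: int = 10_000,
) -> tuple[str, dict[str, str]]:
    """A synthetic single-sample VCF consistent with a synthetic reference.

    Returns ``(vcf_text, reference)`` where *reference* maps seqid to the
    genome sequence the REF alleles were sliced from — exactly what
    ``gvf_to_vcf`` needs to reconstruct indel anchor bases.
    """
    rng = random.Random(seed)
    reference = generate_reference(seed + 1, seqids, region_length)
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={s},length={region_length}>" for s in seqids]
    header += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    body: list[tuple[str, int, str]] = []
    used: dict[str, set[int]] = {s: set() for s in seqids}
    for i in range(n_records):
        seqid = seqids[rng.randrange(len(seqids))]
        while True:
            pos = 10 + rng.randrange(region_length - 100)
            if pos not in used[seqid]:
                used[seqid].add(pos)
                break
        ref_base = reference[seqid][pos - 1]
        kind = rng.randrange(100)
        if kind < 60:  # biallelic SNV
            alts = [_other_base(rng, ref_base)]
            ref = ref_base
        elif kind < 70:  # multiallelic SNV
            a1 = _other_base(rng, ref_base)
            alts = [a1, _other_base(rng, ref_base, a1)]
            ref = ref_base
        elif kind < 85:  # insertion
            ref = ref_base
            alts = [ref_base + _random_seq(rng, 1 + rng.randrange(3))]
        else:  # deletion
            d = 1 + rng.randrange(3)
            ref = reference[seqid][pos - 1 : pos + d]
            alts = [ref_base]
        n_alts = len(alts)
        gt = "1/2" if n_alts == 2 else ("1/1" if rng.randrange(3) == 0 else "0/1")
        reads = [5 + rng.randrange(40) for _ in range(n_alts)]
        ref_reads = 0 if gt == "1/1" else 5 + rng.randrange(40)
        dp = ref_reads + sum(reads)
        ad = ",".join(str(x) for x in [ref_reads, *reads])
        rsid = f"rs{100000 + rng.randrange(900000)}" if rng.randrange(2) else "."
        qual = 20 + rng.randrange(80)
        body.append(
            (
                seqid,
                pos,
                f"{seqid}\t{pos}\t{rsid}\t{ref}\t{','.join(alts)}\t{qual}\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ad}:{dp}",
            )
        )
    body.sort(key=lambda t: (seqids.index(t[0]), t[1]))
    return "\n".join(header + [b[2] for b in body]) + "\n", reference


# ---------------------------------------------------------------------------
# targeted breakage
# ---------------------------------------------------------------------------

def _pick(rng: random.Random, candidates: list) -> object:
    return candidates[rng.randrange(len(candidates))]


def break_document(document: GvfDocument, rule_id: str, seed: int = 0) -> GvfDocument:
    """Return a copy of *document* minimally mutated so that exactly the
    named validator rule fires (all other rules stay silent).

    Raises :class:`GeneratorError` when the document carries nothing the
    rule could act on (e.g. breaking the frequency-alignment rule in a
    document with no Variant_freq attribute).
    """
    if rule_id not in BREAKABLE_RULES:
        raise GeneratorError(f"unknown or unbreakable rule {rule_id!r}")
    doc = copy.deepcopy(document)
    rng = random.Random(seed)
    recs = doc.records

    def need(candidates: list, what: str) -> object:
        if not candidates:
            raise GeneratorError(f"cannot break {rule_id}: no record with {what}")
        return _pick(rng, candidates)

    if rule_id == "R1":
        if len(recs) >= 2:
            i = rng.randrange(len(recs) - 1)
            recs[i + 1].attributes.id = recs[i].attributes.id
        elif recs:
            recs[0].attributes.id = ""
        else:
            raise GeneratorError("cannot break R1: document has no records")
    elif rule_id == "R2":
        doc.pragmas.genome_build = None
    elif rule_id == "R3":
        rec = need(recs, "a type column")
        rec.so_type = "mRNA"  # a sequence_feature term: wrong branch
    elif rule_id == "R4":
        cands = [
            r
            for r in recs
            if r.attributes.variant_seq is not None
            and (r.attributes.variant_reads or r.attributes.variant_freq)
        ]
        rec = need(cands, "aligned Variant_reads/Variant_freq")
        a = rec.attributes
        if a.variant_reads:
            a.variant_reads = a.variant_reads + [0]
        else:
            a.variant_freq = a.variant_freq + [0.5]
    elif rule_id == "R5":
        cands = [r for r in recs if r.attributes.variant_freq]
        rec = need(cands, "Variant_freq")
        rec.attributes.variant_freq[0] = 1.5
    elif rule_id == "R6":
        cands = [r for r in recs if r.attributes.variant_seq is not None]
        rec = need(cands, "Variant_seq")
        a = rec.attributes
        a.variant_effects.append(
            VariantEffect("sequence_variant", len(a.variant_seq), "mRNA", ("ft1",))
        )
    elif rule_id == "R7":
        cands = [r for r in recs if r.attributes.genotype]
        rec = need(cands, "Genotype")
        rec.attributes.genotype = "unknown_zygosity"
    elif rule_id == "R8":
        cands = [r for r in recs if not r.is_insertion and r.end >= r.start]
        rec = need(cands, "a non-insertion span")
        rec.end = rec.start - 1
    elif rule_id == "R9":
        doc.pragmas.file_date = "15-01-2010"
    elif rule_id == "R10":
        cands = [
            r
            for r in recs
            if r.attributes.genotype in ("heterozygous", "homozygous")
            and r.attributes.variant_seq is not None
        ]
        rec = need(cands, "Genotype and Variant_seq")
        a = rec.attributes
        if len(set(a.variant_seq)) >= 2:
            a.genotype = "homozygous"
        else:
            tok = a.variant_seq[0]
            second = "A" if tok != "A" else "C"
            a.variant_seq = a.variant_seq + [second]
            if a.variant_reads is not None:
                a.variant_reads = a.variant_reads + [a.variant_reads[-1]]
                if a.total_reads is not None:
                    a.total_reads += a.variant_reads[-1]
            if a.variant_freq is not None:
                a.variant_freq = a.variant_freq + [a.variant_freq[-1]]
            a.genotype = "homozygous"
    elif rule_id == "R11":
        rec = need(recs, "an attribute column")
        rec.attributes.extra["Xyzzy"] = ["1"]
    elif rule_id == "R12":
        cands = [r for r in recs if r.attributes.variant_seq is not None]
        rec = need(cands, "Variant_seq")
        a = rec.attributes
        a.variant_seq[0] = "J" * max(1, len(a.variant_seq[0]))
    return doc
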