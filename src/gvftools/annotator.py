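"""Populate Variant_effect attributes by intersecting variants with GFF3.

A variant [s1, e1] and a feature [s2, e2] (both 1-based inclusive)
overlap iff ``s1 <= e2 and s2 <= e1``.  Insertions, which occupy no
reference sequence, are treated as stabbing queries at their 5' anchor
base.  Strand is ignored for overlap.

Annotation is additive and idempotent: pre-existing Variant_effect
entries are preserved, and re-annotating with the same feature index adds
no duplicates — a GVF file can accumulate richer annotation with each
analysis pass.  One entry is emitted per (consequence term, allele index,
feature type), with the IDs of all features of that type merged into its
comma-list, so a SNV inside two mRNAs yields a single entry naming both.

Consequence terms come from a configurable *effect map* (feature type ->
SO sequence_variant term).  Codon-level consequences require transcript
translation and are out of scope; the default maps every overlap to the
generic term ``sequence_variant``, and users supply finer terms per
feature type.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Mapping

from intervaltree import IntervalTree

from .errors import ConfigurationError, GvfParseError
from .gvf_io import iter_lines, percent_decode
from .model import GvfDocument, VariantEffect
from .ontology import Ontology

#: Fallback consequence term: any overlap is at least a sequence_variant.
DEFAULT_EFFECT_TERM = "sequence_variant"


@dataclass(frozen=True)
class Feature:
    """One indexed GFF3 feature (1-based inclusive interval)."""

    seqid: str
    start: int
    end: int
    feature_type: str
    feature_id: str


@dataclass
class FeatureIndex:
    """Per-seqid interval index over GFF3 features."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def add(self, feature: Feature) -> None:
        self.features.append(feature)
        tree = self.trees.setdefault(feature.seqid, IntervalTree())
        # intervaltree is half-open; widen the inclusive end by one
        tree.addi(feature.start, feature.end + 1, feature)

    def overlapping(self, seqid: str, start: int, end: int) -> list[Feature]:
        """Features overlapping [start, end] (1-based inclusive), in
        deterministic (start, end, id) order."""
        tree = self.trees.get(seqid)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        hits.sort(key=lambda f: (f.start, f.end, f.feature_id, f.feature_type))
        return hits


def _gff3_attribute(col9: str, tag: str) -> str | None:
    for part in col9.split(";"):
        part = part.strip()
        if part.startswith(tag + "="):
            return percent_decode(part.split("=", 1)[1].split(",")[0])
    return None


def build_feature_index(gff3: str | os.PathLike | IO[str]) -> FeatureIndex:
    """Index a GFF3 annotation file for interval-stabbing queries.

    Features lacking an ID attribute are indexed under a generated
    surrogate (``<type>-line<N>``) and noted in ``index.warnings``.
    """
    index = FeatureIndex()
    for n, text in iter_lines(gff3):
        if not text.strip() or text.startswith("#"):
            if text.startswith("##FASTA"):
                break
            continue
        cols = text.split("\t")
        if len(cols) != 9:
            raise GvfParseError(
                f"expected 9 tab-separated columns, got {len(cols)}", n
            )
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise GvfParseError(f"non-integer feature coordinates", n) from None
        ftype = cols[2]
        fid = _gff3_attribute(cols[8], "ID")
        if fid is None:
            fid = f"{ftype}-line{n}"
            index.warnings.append(f"line {n}: feature without ID, using {fid!r}")
        index.add(Feature(cols[0], start, end, ftype, fid))
    return index


def _resolve_effect_map(
    effect_map: Mapping[str, str] | None, ontology: Ontology | None
) -> Mapping[str, str]:
    effect_map = dict(effect_map or {})
    if ontology is not None:
        for ftype, term in effect_map.items():
            if "sequence_variant" not in ontology.branches(term):
                raise ConfigurationError(
                    f"effect term {term!r} (for feature type {ftype!r}) is not "
                    "in the sequence_variant branch"
                )
    return effect_map


def annotate(
    document: GvfDocument,
    feature_index: FeatureIndex,
    effect_map: Mapping[str, str] | None = None,
    ontology: Ontology | None = None,
) -> GvfDocument:
    """Append Variant_effect entries for every feature each variant hits.

    Modifies *document* in place and returns it.  *effect_map* maps
    feature types to consequence terms (default: everything ->
    ``sequence_variant``); when an *ontology* is given the map is checked
    against the sequence_variant branch up front.
    """
    effect_map = _resolve_effect_map(effect_map, ontology)
    for rec in document.records:
        a = rec.attributes
        start, end = rec.interval()
        if rec.is_insertion:
            end = start  # stab at the 5' anchor base
        hits = feature_index.overlapping(rec.seqid, start, end)
        if not hits:
            continue
        n_alleles = len(a.variant_seq) if a.variant_seq else 1
        # (term, index, type) -> ordered feature-ID list
        merged: dict[tuple[str, int, str], list[str]] = {}
        existing: set[tuple[str, int, str, str]] = set()
        for eff in a.variant_effects:
            for fid in eff.feature_ids:
                existing.add((eff.effect_term, eff.seq_index, eff.feature_type, fid))
        for idx in range(n_alleles):
            for feat in hits:
                term = effect_map.get(feat.feature_type, DEFAULT_EFFECT_TERM)
                key = (term, idx, feat.feature_type)
                if (term, idx, feat.feature_type, feat.feature_id) in existing:
                    continue
                ids = merged.setdefault(key, [])
                if feat.feature_id not in ids:
                    ids.append(feat.feature_id)
        for (term, idx, ftype), ids in merged.items():
            a.variant_effects.append(VariantEffect(term, idx, ftype, tuple(ids)))
    return document
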