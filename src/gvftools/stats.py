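"""Summary statistics over a GVF document.

Counts records per alteration type and per seqid, tallies genotypes, and
classifies single-base substitutions as transitions (purine<->purine or
pyrimidine<->pyrimidine: A<->G, C<->T) versus transversions — the
standard SNV quality statistic.  Ts/Tv is counted per variant allele over
records whose reference and variant sequences are both single bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import GvfDocument

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_SINGLE_BASES = set("ACGT")


@dataclass
class GvfStats:
    n_records: int
    type_counts: "pd.Series[int]"
    seqid_counts: "pd.Series[int]"
    genotype_counts: "pd.Series[int]"
    transitions: int
    transversions: int

    @property
    def ts_tv(self) -> float | None:
        """Transition/transversion ratio, or None when undefined."""
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions

    def to_frame(self) -> pd.DataFrame:
        """Long-form summary table (section, key, count)."""
        rows = [("total", "records", self.n_records)]
        for section, series in (
            ("type", self.type_counts),
            ("seqid", self.seqid_counts),
            ("genotype", self.genotype_counts),
        ):
            rows.extend((section, str(k), int(v)) for k, v in series.items())
        rows.append(("substitution", "transitions", self.transitions))
        rows.append(("substitution", "transversions", self.transversions))
        return pd.DataFrame(rows, columns=["section", "key", "count"])


def compute_stats(document: GvfDocument) -> GvfStats:
    """Tally a document; an empty document yields all-zero tables."""
    types: dict[str, int] = {}
    seqids: dict[str, int] = {}
    genotypes: dict[str, int] = {}
    ts = tv = 0
    for rec in document.records:
        types[rec.so_type] = types.get(rec.so_type, 0) + 1
        seqids[rec.seqid] = seqids.get(rec.seqid, 0) + 1
        a = rec.attributes
        if a.genotype:
            genotypes[a.genotype] = genotypes.get(a.genotype, 0) + 1
        ref = a.reference_seq
        if ref in _SINGLE_BASES and a.variant_seq:
            for token in a.variant_seq:
                if token in _SINGLE_BASES and token != ref:
                    if frozenset((ref, token)) in _TRANSITIONS:
                        ts += 1
                    else:
                        tv += 1
    return GvfStats(
        n_records=len(document.records),
        type_counts=pd.Series(types, dtype=int).sort_index(),
        seqid_counts=pd.Series(seqids, dtype=int).sort_index(),
        genotype_counts=pd.Series(genotypes, dtype=int).sort_index(),
        transitions=ts,
        transversions=tv,
    )
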