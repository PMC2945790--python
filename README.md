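# gvftools

A Python toolkit for the **Genome Variation Format (GVF)** — the
Sequence-Ontology-typed extension of GFF3 for describing DNA sequence
variants relative to a reference genome.

Personal-genome variant calls are exchanged as "variant files", and
without a shared format every provider's tab-delimited dialect needs its
own parser before any comparative analysis can start.  GVF solves this by
building on GFF3: the eight fixed columns (seqid, source, type, start,
end, score, strand, phase) locate a sequence alteration on the reference,
the type column is constrained to Sequence Ontology (SO)
*sequence_alteration* terms (`SNV`, `insertion`, `deletion`,
`duplication`, ...), and the ninth column carries eleven variant-specific
`Tag=Value` attributes (`ID`, `Variant_seq`, `Reference_seq`,
`Variant_reads`, `Total_reads`, `Genotype`, `Variant_freq`,
`Variant_effect`, `Variant_copy_number`, `Reference_copy_number`,
`Nomenclature`) plus nine file-level `##` pragmas for provenance
(genome build, individual, calling method, platform, ploidy, ...).  The
four-field `Variant_effect` attribute

```
Variant_effect = <sequence_variant term> <0-based allele index> <sequence_feature term> <feature IDs>
```

links each variant allele to the annotated features it intersects and the
consequence it has there, with both terms drawn from SO branches so the
file contents are machine-reasonable.

The toolkit is intended for people who produce, exchange, or audit
variant files: it provides the data model, a streaming parser and
deterministic writer, the full validation rule set (13 line-tagged rules,
R1–R13), an `is_a`-closure ontology engine with a bundled SO subgraph,
VCF↔GVF and tabular→GVF converters, a feature-intersection annotator
that populates `Variant_effect`, summary statistics (including the
transition/transversion ratio), seeded synthetic data with targeted
rule breakage, and the catalogue of the public 10Gen reference dataset.

## Worked example

Generate a small synthetic variant file, validate it, and summarize it:

```sh
$ gvf generate --seed 4 --n-records 8 -o demo.gvf
$ head -n 12 demo.gvf
##gff-version 3
##genome-build NCBI B36
##file-version 1.0
##file-date 2010-01-15
##individual-id Dbxref = synthetic:IND-004;Gender = male
##source-method Source = synth;Type = SNV;Comment = simulated caller
##technology-platform Source = synth;Type = SNV;Platform_class = short read sequencing;Platform_name = simulated
##ploidy chr1 1 1000000 diploid
##ploidy chr2 1 1000000 diploid
##ploidy chr3 1 1000000 diploid
##ploidy chrX 1 1000000 haploid
chr1	synth	SNV	318032	318032	17	+	.	ID=chr1:synth:SNV:318032;Variant_seq=T,C;Reference_seq=A;Variant_reads=10,9;Total_reads=19;Genotype=heterozygous;Variant_freq=0.26,0.36
```

The first feature line reads: a heterozygous SNV at chr1:318032 where the
reference base `A` was observed as two alternate alleles `T` and `C`,
supported by 10 and 9 of 19 covering reads.  Validation applies the full
rule set and exits 0 iff no error-severity diagnostic fired:

```sh
$ gvf validate demo.gvf ; echo "exit=$?"
severity	rule	line	message
exit=0

$ gvf stats demo.gvf
     section           key  count
       total       records      8
        type           SNV      6
        type      deletion      1
        type   duplication      1
       ...
ts/tv: 0.14
```

The type histogram counts records per SO alteration term and `ts/tv` is
the transition/transversion ratio over single-base substitutions (0.14
here — a uniform random allele generator draws roughly one transition per
two transversions, unlike real genomes where ts/tv ≈ 2).

The same operations are available as a library:

```python
from gvftools import parse, validate, load_bundled
doc = parse("demo.gvf")
report = validate(doc, load_bundled())
assert report.is_valid
```

Converters (`gvf convert vcf2gvf / gvf2vcf / table2gvf`) map VCF sites to
GVF coordinates with shared-prefix trimming, and the annotator
(`gvf annotate variants.gvf features.gff3`) fills in `Variant_effect`
from overlapping GFF3 features.

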