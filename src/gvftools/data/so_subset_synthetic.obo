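format-version: 1.2
ontology: so-subset-synthetic
default-namespace: sequence
remark: Synthetic hand-curated subset of the Sequence Ontology covering the three branches used to type genome-variation files (sequence_alteration, sequence_feature, sequence_variant). Built for this toolkit's bundled use; accessions follow the public SO where applicable but term counts do not track any SO release.

[Term]
id: SO:0001059
name: sequence_alteration

[Term]
id: SO:1000002
name: substitution
is_a: SO:0001059 ! sequence_alteration

[Term]
id: SO:1000008
name: point_mutation
is_a: SO:1000002 ! substitution

[Term]
id: SO:0001483
name: SNV
synonym: "single nucleotide variant" EXACT []
is_a: SO:1000008 ! point_mutation

[Term]
id: SO:0001013
name: MNP
is_a: SO:1000002 ! substitution

[Term]
id: SO:1000005
name: complex_substitution
is_a: SO:1000002 ! substitution

[Term]
id: SO:0000667
name: insertion
is_a: SO:0001059 ! sequence_alteration

[Term]
id: SO:0000159
name: deletion
is_a: SO:0001059 ! sequence_alteration

[Term]
id: SO:1000032
name: indel
is_a: SO:0001059 ! sequence_alteration

[Term]
id: SO:1000035
name: duplication
is_a: SO:0000667 ! insertion

[Term]
id: SO:1000173
name: tandem_duplication
is_a: SO:1000035 ! duplication

[Term]
id: SO:1000036
name: inversion
is_a: SO:0001059 ! sequence_alteration

[Term]
id: SO:0000199
name: translocation
is_a: SO:0001059 ! sequence_alteration

[Term]
id: SO:0001019
name: copy_number_variation
is_a: SO:0001059 ! sequence_alteration

[Term]
id: SO:0001742
name: copy_number_gain
is_a: SO:0001019 ! copy_number_variation

[Term]
id: SO:0001743
name: copy_number_loss
is_a: SO:0001019 ! copy_number_variation

[Term]
id: SO:0000110
name: sequence_feature

[Term]
id: SO:0000001
name: region
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000704
name: gene
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000673
name: transcript
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000234
name: mRNA
is_a: SO:0000673 ! transcript

[Term]
id: SO:0000147
name: exon
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000188
name: intron
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000316
name: CDS
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000203
name: UTR
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000204
name: five_prime_UTR
is_a: SO:0000203 ! UTR

[Term]
id: SO:0000205
name: three_prime_UTR
is_a: SO:0000203 ! UTR

[Term]
id: SO:0000162
name: splice_site
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000315
name: transcription_start_site
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000340
name: chromosome
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0001060
name: sequence_variant

[Term]
id: SO:0001537
name: structural_variant
is_a: SO:0001060 ! sequence_variant

[Term]
id: SO:0001628
name: intergenic_variant
is_a: SO:0001060 ! sequence_variant

[Term]
id: SO:0001564
name: gene_variant
is_a: SO:0001060 ! sequence_variant

[Term]
id: SO:0001576
name: transcript_variant
is_a: SO:0001564 ! gene_variant

[Term]
id: SO:0001580
name: coding_sequence_variant
is_a: SO:0001576 ! transcript_variant

[Term]
id: SO:0001583
name: non_synonymous_codon
synonym: "missense_variant" EXACT []
is_a: SO:0001580 ! coding_sequence_variant

[Term]
id: SO:0001588
name: synonymous_codon
synonym: "synonymous_variant" EXACT []
is_a: SO:0001580 ! coding_sequence_variant

[Term]
id: SO:0001587
name: stop_gained
is_a: SO:0001580 ! coding_sequence_variant

[Term]
id: SO:0001589
name: frameshift_variant
is_a: SO:0001580 ! coding_sequence_variant

[Term]
id: SO:0001627
name: intron_variant
is_a: SO:0001576 ! transcript_variant

[Term]
id: SO:0001629
name: splice_site_variant
is_a: SO:0001576 ! transcript_variant

[Term]
id: SO:0001622
name: UTR_variant
is_a: SO:0001576 ! transcript_variant

[Term]
id: SO:0001623
name: 5_prime_UTR_variant
is_a: SO:0001622 ! UTR_variant

[Term]
id: SO:0001624
name: 3_prime_UTR_variant
is_a: SO:0001622 ! UTR_variant

[Term]
id: SO:9999001
name: obsolete_variation_kind
is_obsolete: true
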