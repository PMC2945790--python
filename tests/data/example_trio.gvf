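##gff-version 3
##genome-build NCBI B36
##file-version 1.0
##file-date 2010-01-15
##individual-id Dbxref = synthetic:IND-001;Gender = male
##source-method Seqid = chr1;Source = Soap;Type = SNV;Comment = simulated caller
##technology-platform Source = Soap;Type = SNV;Platform_class = short read sequencing;Platform_name = simulated
##ploidy chr1 1 249250621 diploid
# hand-written example document: an SNV, a deletion and a duplication
chr1	Soap	SNV	12345	12345	.	+	.	ID=chr1:Soap:SNP:12345;Variant_seq=A,T;Reference_seq=G;Variant_reads=34,23;Total_reads=57;Genotype=heterozygous
chr1	synth	deletion	20010	20012	.	+	.	ID=chr1:synth:deletion:20010;Variant_seq=-;Reference_seq=TCA;Genotype=homozygous
chr2	synth	duplication	88000	89200	.	+	.	ID=chr2:synth:duplication:88000;Variant_copy_number=7;Reference_copy_number=5
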