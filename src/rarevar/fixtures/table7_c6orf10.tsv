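# The 14 low-frequency variants found by Sanger sequencing of the C6orf10
# 3' exon (chr6:32261295-32260757, 538 bp span) in the 120-patient cohort.
# Consequence derived from the amino-acid change notation: "stop" ->
# stop_gained, "Xfr" -> frameshift, identical residues -> synonymous,
# otherwise missense. Panel frequencies are percents as printed; "-" means
# the variant is absent from that panel.
chrom	pos	variant_id	aa_change	consequence	nt_change	maf_pct_dbsnp	maf_pct_exac	maf_pct_gnomad	alt_alleles	n_alleles	maf_pct_cohort
6	32260761	-	Glu561Asp	missense	C>G	-	-	-	1	240	0.42
6	32260769	-	Val559Leu	missense	C>G	-	-	-	1	240	0.42
6	32260774	-	Lys557Ile	missense	T>A	-	-	-	1	240	0.42
6	32260878	-	Asp522Asp	synonymous	G>A	-	-	-	3	240	1.25
6	32260898	-	Asp516Tyr	missense	C>A	-	-	-	1	240	0.42
6	32260927	-	Glu506Val	missense	T>A	-	-	-	1	240	0.42
6	32260933	rs766126891	Asp504Val	missense	T>A	0.001	-	-	1	240	0.42
6	32261014	rs7751028	Gly477Val	missense	C>A	2.480	0.98	0.99	1	240	0.42
6	32261075	-	Lys457stop	stop_gained	T>A	-	-	-	1	240	0.42
6	32261084	-	Ser454Xfr	frameshift	A>insG	-	-	-	1	240	0.42
6	32261093	-	Gly451stop	stop_gained	C>A	-	-	-	1	240	0.42
6	32261158	rs114543649	Thr429Ser	missense	G>C	2.479	0.98	0.99	1	240	0.42
6	32261277	-	Ser389Xfr	frameshift	T>delT	-	-	-	2	240	0.83
6	32261291	-	Gln385Glu	missense	G>C	2.482	0.98	0.99	1	240	0.42
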