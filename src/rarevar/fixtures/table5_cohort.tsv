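# The 15 family-selected candidate variants screened in the 120-patient
# unrelated MS cohort (240 alleles). alt_alleles is the printed cohort
# allele count; panel frequencies are 2-decimal percents as printed, "-"
# when the panel does not report the variant.
#tuscany n_alleles=214
gene	chrom	pos	variant_id	consequence	aa_change	nt_change	alt_alleles	n_alleles	maf_pct_cohort	maf_pct_tuscany	maf_pct_dbsnp	maf_pct_exac	maf_pct_gnomad
ADAMTS3	4	73414590	-	missense	Lys37Glu	T>C	0	240	0	-	-	-	-
ANKRD55	5	55407449	rs77017041	missense	Ser376Pro	A>G	0	240	0	0.47	0.427	0.63	0.71
C6orf10	6	32261153	rs16870005	missense	Ala431Thr	C>T	9	240	3.75	1.4	1.250	1.43	0.85
CD86	3	121774281	rs11575853	utr5	-	A>G	9	240	3.75	2.8	1.078	-	3.1
EVI5	1	92979432	rs41286809	synonymous	Phe749Phe	G>A	2	240	0.83	0.47	1.116	1.55	1.61
GC	4	72669661	rs76781122	start_lost	Met1Ile	G>T	11	240	4.58	5.61	1.611	3.35	2.77
IL2RA	10	6054765	rs12722600	utr3	-	G>A	19	240	7.92	4.21	1.777	-	0.87
MALT1	18	56367823	rs74847855	missense	Arg217Gly	A>G	11	240	4.58	1.9	3.734	4.28	4.20
MMEL1	1	2530169	rs147248515	missense	Pro368Thr	G>T	0	240	0	0	0.022	0.028	0.037
STAT4	2	191899319	-	synonymous	Gln525Gln	A>G	0	240	0	-	-	-	-
TET2	4	106156163	rs61744960	missense	Gly355Asp	G>A	20	240	8.33	5.6	2.614	3.77	3.69
TOP3A	17	18217958	rs2230153	synonymous	Ala45Ala	G>A	4	240	1.66	0.47	1.692	0.46	0.36
TRAF3	14	103371923	rs138943371	synonymous	Ser478Ser	C>T	3	240	1.25	0.47	0.245	0.30	0.36
TYK2	19	10472452	rs12720355	synonymous	Ile651Ile	C>T	4	240	1.66	1.4	0.962	1.38	1.45
WWOX	16	78458807	rs7201683	missense	Leu216Val	C>G	5	240	2.08	0.47	1.989	1.23	1.11
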