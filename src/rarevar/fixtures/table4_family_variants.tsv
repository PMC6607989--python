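# Low-frequency variants identified by WES in the three MS families, with
# per-member carrier lists. Frequencies are 2-decimal percents as printed;
# "-" means not reported by the panel; a printed 0 means the panel does not
# carry the variant. The row flagged ambiguous=1 duplicates the ADAMTS3
# 4:73414590 site with an unprefixed carrier label and is excluded from the
# 20-variant working set.
gene	chrom	pos	variant_id	maf_pct_dbsnp	maf_pct_exac	maf_pct_gnomad	consequence	carriers	ambiguous
ADAMTS3	4	73178175	rs150270324	0.926	1.34	1.12	missense	A-I-2,A-II-3	0
ADAMTS3	4	73414590	-	-	-	0	missense	II-3	1
ADAMTS3	4	73414590	-	-	0	0	missense	B-I-1,B-II-3,B-II-4	0
ANKRD55	5	55407449	rs77017041	0.427	0.63	0.71	missense	C-I-2,C-II-3	0
BTNL2	6	32363893	rs28362679	1.825	-	0	missense	B-I-1,C-I-1,C-I-2	0
C6orf10	6	32261153	rs16870005	1.250	1.43	0.85	missense	B-I-2,B-II-3	0
GC	4	72669661	rs76781122	1.611	3.35	2.77	missense	B-I-2,B-II-3	0
MALT1	18	56367823	rs74847855	3.734	4.28	4.20	missense	B-I-2,B-II-3,B-II-4	0
MMEL1	1	2530169	rs147248515	0.022	0.028	0.037	missense	B-I-2,B-II-3	0
TET2	4	106156163	rs61744960	2.641	3.77	3.69	missense	B-I-2,B-II-3,C-I-2,C-II-3,A-I-1,A-II-4	0
WWOX	16	78458807	rs7201683	1.989	1.23	1.11	missense	B-I-2,B-II-3,B-II-4,C-I-2	0
EVI5	1	92979432	rs41286809	1.116	1.55	1.61	synonymous	C-I-2,C-II-3,A-I-1,A-II-3,A-II-4	0
GC	4	72620788	rs76803094	1.799	2.56	2.14	synonymous	B-I-1,B-II-3,B-II-4	0
GEMIN2	14	39587220	rs150986614	0.251	0.37	0.37	synonymous	A-I-2,A-II-3,A-II-4	0
STAT4	2	191899319	-	-	-	-	synonymous	C-I-2,C-II-3	0
TRAF3	14	103371923	rs138943371	0.245	0.30	0.36	synonymous	C-I-2,C-II-3	0
TOP3A	17	18217958	rs2230153	1.692	0.46	0.36	synonymous	C-I-2,C-II-3,A-I-2	0
TYK2	19	10472452	rs12720355	0.962	1.38	1.45	synonymous	C-I-2,C-II-3	0
CD86	3	121774281	rs11575853	1.078	-	3.1	utr5	B-I-2,B-II-3,C-I-1	0
IL2RA	10	6054765	rs12722600	1.777	-	0.87	utr3	B-I-2,B-II-3,C-I-1,C-II-3	0
RRAS2	11	14300827	-	-	-	-	utr3	B-I-2,B-II-4	0
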