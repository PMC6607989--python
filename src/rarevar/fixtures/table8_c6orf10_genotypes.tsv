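# Per-patient genotypes at the 14 C6orf10 3'-exon low-frequency variants.
# "variants" is a semicolon-separated list of aa_change:genotype pairs.
patient_id	gender	onset	phenotype	variants
138 ZM	F	21	RR	Ser454Xfr:Het
221 ZM	M	22	RR	Val559Leu:Het;Glu561Asp:Het
150 ZM	F	25	RR	Ser389Xfr:Hom
194 ZM	F	31	RR	Gln385Glu:Het;Thr429Ser:Het;Gly477Val:Het
106 ZM	M	32	SP	Asp504Val:Het;Asp522Asp:Het
128 ZM	F	32	RR	Glu506Val:Het
109 ZM	F	37	SP	Asp522Asp:Het
115 ZM	F	38	SP	Lys457stop:Het
MS23	F	38	RR	Gly451stop:Het
112 ZM	F	41	RR	Lys557Ile:Het
25-WP3	F	51	PP	Asp516Tyr:Het
65-WP3	F	51	SP	Asp522Asp:Het
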