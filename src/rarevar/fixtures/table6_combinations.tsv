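# Unrelated MS patients carrying at least two of the 15 screened
# low-frequency variants. Cells are Het/Hom; empty means non-carrier.
patient_id	gender	onset	phenotype	C6orf10_rs16870005	CD86_rs11575853	EVI5_rs41286809	GC_rs76781122	IL2RA_rs12722600	MALT1_rs74847855	TET2_rs61744960	TOP3A_rs2230153	TRAF3_rs138943371	TYK2_rs12720355	WWOX_rs7201683
132 ZM	F	20	RR							Het	Het
159 ZM	M	26	RR							Het	Het
173 ZM	F	31	RR							Het	Het
194 ZM	F	31	RR				Het	Hom						Het
27-WP3	M	31	SP	Het			Het
43-WP3	F	31	PP		Het			Het
155 ZM	F	33	SP							Het		Het
51-WP3	M	33	SP	Het						Het
109 ZM	F	37	SP		Het	Het
63-WP3	F	37	SP	Het	Het					Het
115 ZM	F	38	SP						Het	Het				Het
69-WP3	M	40	SP				Het		Het
111 ZM	F	41	RR	Het				Het		Het
49-WP3	F	42	PP				Het	Het
57-WP3	M	42	SP	Het				Het					Het
208 ZM	F	44	RR					Het						Het
MS18	F	45	SP		Het							Hom
184 ZM	M	47	SP					Het						Het
192 ZM	F	48	RR	Het				Het
72-WP3	F	48	PP						Het	Het
204 ZM	M	50	RR					Het	Het
MS07	M	nd	SP		Het						Het
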