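# Three nuclear families (A-C), 11 WES-sequenced members: 7 affected, 4
# unaffected. The published pedigree figure does not state affection as
# text; the affection labels below are BACK-DERIVED as the unique
# assignment consistent with the published carrier lists, the
# nine-affected-only and the fourteen-transmitted variant counts. They are
# a reconstruction, not a quotation.
A	A-I-1	0	0	1	2
A	A-I-2	0	0	2	1
A	A-II-3	A-I-1	A-I-2	0	2
A	A-II-4	A-I-1	A-I-2	0	2
B	B-I-1	0	0	1	1
B	B-I-2	0	0	2	2
B	B-II-3	B-I-1	B-I-2	0	2
B	B-II-4	B-I-1	B-I-2	0	1
C	C-I-1	0	0	1	1
C	C-I-2	0	0	2	2
C	C-II-3	C-I-1	C-I-2	0	2
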