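gene	contig	pos	kind	sequence
CYP4A22	1	47384338	deletion	T
KCNA10	1	110861798	insertion	GAGCAAC
OBSCN	1	22657241	insertion	T
ARID4B	1	233411716	deletion	A
CCDC120	X	48811750	deletion	TCGTAGC
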