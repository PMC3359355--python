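gene	chrom	position	codon_index	ref_codon	ref_aa	mut_codon	mut_aa	type	sift	polyphen
MAP4K2	11	64313974	761	AGC	S	ATC	I	nsSNP	Damaging	Possibly damaging
TAOK2	16	29898286	204	GGC	G	GAC	D	nsSNP	Tolerated	Possibly damaging
TP53	17	7519128	176	TGC	C	TTC	F	nsSNP	Damaging	Possibly damaging
SIN3B	19	16834366	421	AAG	K	ATG	M	nsSNP	Damaging	Possibly damaging
NLRC4	2	32329712	242	AGG	R	AAG	K	nsSNP	Tolerated	Benign
KDR	4	55671617	351	CCT	P	CTT	L	nsSNP	Damaging	Possibly damaging
MYC	8	128820394	235	CCC	P	CTC	L	nsSNP	DamagingLC*	Possibly damaging
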