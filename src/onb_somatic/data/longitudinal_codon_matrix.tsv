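date	site	MYC	KDR	TAOK2	MAP4K2	SIN3B	TP53	NLRC4
2008-06-02	Left nasal mass	CCC	AGG	GAC	ATC	AAG	TTC	AGG
2008-06-02	Right nasal mass	CCC	AGG	GAC	ATC	AAG	TTC	AGG
2008-06-12	Frontal tumor	CCC	AGG	GAC	ATC	AAG	TTC	AGG
2008-06-12	Nasal tumor	CCC	N/A	GAC	ATC	AAG	TTC	AGG
2010-07-26	Right cheek	CTC	AAG	GAC	ATC	ATG	TTC	AAG
2010-07-26	Right cheek (second section)	CTC	AAG	GAC	ATC	ATG	TTC	AAG
2010-11-03	Right cheek (WGS)	CTC	AAG	GAC	ATC	ATG	TTC	AAG
reference	reference	CCC	AGG	GGC	AGC	AAG	TGC	AGG
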