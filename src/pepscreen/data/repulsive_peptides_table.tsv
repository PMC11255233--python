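rank	protein	peptide
1	SFRP1	KQQ
2	SFRP1	PNATEASKP
3	SFRP1	EVK
4	SFRP1	AIHKWDKKN
5	DKK1	SVLNSNAIK
6	DKK1	VSAAP
7	DKK1	TLSSKMYHTKGQ
8	DKK1	WSKICKPVLKE
9	TNF-alpha	AEEALPKK
10	TNF-alpha	VRSSSRTP
11	TNF-alpha	SDKKPVAHVVANPQAE
12	TNF-alpha	YQTKV
13	TNF-alpha	PCQRETPEGAEAKP
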