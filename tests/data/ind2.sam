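@HD	VN:1.6	SO:coordinate
@SQ	SN:chr1	LN:10000
s01	0	chr1	95	60	10M	*	0	0	CCCCCACCCC	IIIIIIIIII	NH:i:1
s02	0	chr1	95	60	10M	*	0	0	CCCCCACCCC	IIIIIIIIII	NH:i:1
s03	0	chr1	95	60	10M	*	0	0	CCCCCACCCC	IIIIIIIIII	NH:i:1
s04	0	chr1	95	60	10M	*	0	0	CCCCCACCCC	IIIIIIIIII	NH:i:1
s05	0	chr1	95	60	10M	*	0	0	CCCCCGCCCC	IIIIIIIIII	NH:i:1
s06	0	chr1	195	60	10M	*	0	0	AAAAACAAAA	IIIIIIIIII	NH:i:1
s07	0	chr1	195	60	10M	*	0	0	AAAAATAAAA	IIIIIIIIII	NH:i:1
s08	0	chr1	195	60	10M	*	0	0	AAAAATAAAA	IIIIIIIIII	NH:i:1
s09	0	chr1	195	60	10M	*	0	0	AAAAATAAAA	IIIIIIIIII	NH:i:1
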