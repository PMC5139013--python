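@HD	VN:1.6	SO:coordinate
@SQ	SN:chr1	LN:10000
r03	0	chr1	93	60	10M	*	0	0	CCCCCCCACC	IIIIIIIIII	NH:i:1
r01	0	chr1	95	60	10M	*	0	0	CCCCCACCCC	IIIIIIIIII	NH:i:1
r04	0	chr1	95	60	10M	*	0	0	CCCCCGCCCC	IIIIIIIIII	NH:i:1
r06	0	chr1	95	60	10M	*	0	0	CCCCCTCCCC	IIIIIIIIII	NH:i:1
r08	0	chr1	95	60	5M2D5M	*	0	0	CCCCCCCCCC	IIIIIIIIII	NH:i:1
r09	0	chr1	95	3	10M	*	0	0	CCCCCACCCC	IIIIIIIIII	NH:i:2
r10	0	chr1	95	0	10M	*	0	0	CCCCCACCCC	IIIIIIIIII
r02	0	chr1	96	60	10M	*	0	0	CCCCACCCCC	IIIIIIIIII	NH:i:1
r07	0	chr1	96	60	5S10M	*	0	0	CCCCCCCCCACCCCC	IIIIIIIIIIIIIII	NH:i:1
r05	0	chr1	98	60	10M	*	0	0	CCGCCCCCCC	IIIIIIIIII	NH:i:1
r11	0	chr1	195	60	10M	*	0	0	AAAAACAAAA	IIIIIIIIII	NH:i:1
r13	0	chr1	195	60	10M	*	0	0	AAAAATAAAA	IIIIIIIIII	NH:i:1
r12	0	chr1	196	60	10M	*	0	0	AAAACAAAAA	IIIIIIIIII	NH:i:1
r14	0	chr1	198	60	10M	*	0	0	AATAAAAAAA	IIIIIIIIII
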