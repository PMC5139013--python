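snp_id	chrom	pos	ref	alt	mappability
rs1	chr1	100	A	G	1.0
rs2	chr1	200	C	T	1.0
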