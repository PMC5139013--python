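snp_id	ind1	ind2
rs1	1	1
rs2	1	1
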