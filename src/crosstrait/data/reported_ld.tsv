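snp_a	snp_b	r2
rs4765914	rs10774037	0.99
rs16836940	rs2318763	0.39
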