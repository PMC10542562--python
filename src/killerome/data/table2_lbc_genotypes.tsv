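pcr_genotype	n_hi	n_lo
0,0,1	1	2
0,1,0	0	49
0,1,1	13	3
1,0,0	0	0
1,0,1	5	2
1,1,0	0	1
1,1,1	14	10
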