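virus	n_strains	n_primer_pairs	n_pcr_genotypes
L-A	30	7	6
L-BC	100	3	6
20S	26	2	3
23S	14	2	3
M1	5	2	1
M2	3	2	1
M28	0	2	
Mlus	7	5	1
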