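strain_id	m_species	gel_band_kb	killer
YJM1077	M1		K1+
YJM1290	M1		K1+
YJM1307	M1	2.5	K1+
YJM1387	M1		K1+/-
YJM1419	M1		K1-
YJM453	M2	1.7	K2+
YJM1341	M2		K2+
YJM1574	M2		K2+
YJM145	Mlus	2.5	Klus-
YJM320	Mlus	2.5	Klus+
YJM975	Mlus	2.5	Klus-
YJM978	Mlus	2.5	Klus-
YJM993	Mlus	2.5	Klus-
YJM1133	Mlus	2.5	Klus+
YJM1526	Mlus	2	Klus+
YJM195	0	3	K-
YJM681	0	2.5	K-
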