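chromosome	gene	log2_copy_number	log2_fc	band
1	FCGR3A	1.13334	3.91384	q23.3
1	FCGR2B	1.14834	2.52075	q23.3
1	AMY2A	1.06865	2.50174	p21.1
1	AMY2B	1.58959	1.94116	p21.1
1	CFH	1.06624	1.47934	q31.3
1	LCE1D	1.23411	1.41679	q21.3
1	CFHR3	1.20817	1.35526	q31.3
3	TP63	1.04434	3.18336	q28
3	MUC4	1.35013	2.38177	q29
3	MUC20	1.63525	2.25619	q29
4	TMPRSS11E	1.11569	1.78099	p16.3
5	ZDHHC11	1.07998	1.03782	q14.1
6	HLA-DQA1	1.12618	1.73272	p21.32
7	ARHGEF5	1.07093	1.46641	q35
16	CES1	1.68967	2.06824	q12.2
19	LILRB5	1.08841	1.39769	q13.42
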