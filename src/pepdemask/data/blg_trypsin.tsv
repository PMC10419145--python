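bond_index	label	motif	selectivity_pct	lag_ratio	k_rel	demask_class	is_fast
8	8	MK-GL	13.7	0.0	1.0	one_stage	true
14	14	QK-DL	7.4	0.33	1.2	one_stage	false
20	20	WY-SL		2.08	0.02	excluded	false
40	40	LR-VY	9.9	0.15	3.1	one_stage	false
60	60	QK-WE	0.2	2.00	0.01	excluded	false
69	69/70		10.1		2.1	one_stage	true
75	75	EK-TK	9.1	0.32	0.8	one_stage	true
83	83	FK-ID	2.9	1.21	0.4	two_stage	false
91	91	NK-VL	3.8	0.89	0.5	two_stage	false
101	100/101		3.6	0.85	1.1	two_stage	true
124	124	VR-TP	5.0	1.36	0.5	two_stage	false
135	135	EK-FD	1.6	1.94	0.05	two_stage	false
138	138	DK-AL	5.3	0.27	1.4	one_stage	true
141	141	LK-AL	9.4	0.18	2.3	one_stage	true
148	148	IR-LS	11.0	0.14	3.5	one_stage	true
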