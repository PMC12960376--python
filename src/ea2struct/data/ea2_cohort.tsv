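patient_id	family_id	FSIQ	VCI	PRI	WMI	PSI	tm_score	hgvs_c	hgvs_p	predicted_length	wildtype_length
P1	F1	101	90	103	109	110	0.816	c.5569C>T	p.R1857*	1856	2261
P2	F1	99	100	94	125	81	0.816	c.5569C>T	p.R1857*	1856	2261
P3	F2	86	90	103	93	75	0.838	c.2762C>G;c.5569C>T	p.A921G, p.R1857*	1856	2261
P4	F3	83	76	96	81	98	0.716	c.4953+1G>A	unknown	1736	2261
P5	F4	80	77	88	98	81	0.741	c.3871_3873delGAG	p.E1291del	2260	2261
P6	F4	80	86	84	83	92	0.741	c.3871_3873delGAG	p.E1291del	2260	2261
P7	F5	80	83	92	90	78	0.795	c.3169C>T;c.5509delG	p.A1057C, p.A1837Pfs*22	1857	2261
P8	F6	77	88	74	75	97	0.780	c.5455C>T	p.R1819*	1818	2261
P9	F3	67	74	68	78	84	0.716	c.4953+1G>A	unknown	1736	2261
P10	F7	66	70	76	69	84	0.624	c.3679_3681delinsG	p.L1227Vfs*20	1245	2261
P11	F8	65	76	70	87	66	0.753	c.757C>T	p.H253Y	2261	2261
P12	F9	64	68	76	78	66	0.712	c.3414dup	p.K1139Qfs*6	1143	2261
P13	F3	63	72	72	63	78	0.716	c.4953+1G>A	unknown	1736	2261
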