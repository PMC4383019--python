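id	age	sex	stage	type	grade	modality	mseq	coverage_gt30x	snv_count	dn_ds	ts_tv	gains	deletions	total_changes
P01	38	M	T1bN2Mx	1/2/CDC	3	1		94.0	45	1.72	0.78	1q,2p,17q	3p,6q,11q,13q,14q,21q	9
P02	85	F	T3aN2MX	2	3	1		93.5	57	2.36	0.82	1q,2,6p,7,12p,13q,16q,17q,18p,19q	3p,17p,18q	12
P03	86	F	T1bNXMX	2	2	1		93.3	44	1.98	1.08	7,8,16,17,20	X	6
P04	55	M	T3bN2MX	1/2	3	1		82.4	55	1.75	1.89			0
P05	57	M	T1aNXMX	2	2	1		93.3	2	0.50	1.00	7,16,17,21q	9p,X	6
P06	62	M	T1aN0M0	2	3	1		94.9	87	2.67	0.58	3q,7,12,16,17	X	6
P07	38	F	T1aN0M0	2	2	1		93.8	185	1.87	0.24			0
P08	72	M	T3aNXMX	1/2	3	2		83.1	30	3.00	1.69	7,16p		2
P09	75	M	T1aN0MX	2	3	2		78.7	79	3.95	1.06	2q	1p,2p,2q,3p,3q,4q,6p,7q,9,18,20p	12
P10	63	F	T2N0MX	1/2	3	2		82.8	77	2.19	0.94	2,3,5,7,12,16,17		7
P11	30	F	T1aN0MX	2	3	2		81.7	63	3.68	1.32		14q,21q,22q	3
P12	44	F	T2NXMX	2	3	2		84.3	46	1.28	2.15			0
P13	76	M	T2NXMX	2	3	2		78.2	94	2.56	0.89	12,16,17		3
P14	62	M	T2NXMX	2	3	2		85.6	71	1.98	0.97	7,16,17,20	X	5
P15	57	F	T1aNXMX	2	3	2		77.3	83	2.56	0.66	16,17q		2
P16	48	M	T1aNXMX	2	1	3		90.5	42	3.46	1.27	7,16,17		3
P17	44	F		2	3	3		91.2	243	1.68	1.77	2q,5,7,12,16,17	3p	7
P18	46	F	T1NXMX	2	2	3		89.1	64	4.22	1.04			0
P19	60	M	T1NXMX	2	2	3		85.7	5	0.63	1.12	7		1
P20	63	M	T1aNXMX	2	3	3		87.3	77	3.20	0.72	17		1
P21	87	F	T2NXMX	2	2	3		89.9	100	2.46	0.71	3,8,12,16	3p,9,11,18,22	9
P22	76	M	T3bNXMX	1/2	2	3		84.9	75	2.90	0.95	7,12,17,20	3,18	5
P23	80	M	T3bN0MX	2	3	3		90.0	95	3.32	0.90	1q,9,16p,17q	2p,2q	6
RK30	38	F	T1bN0M0	1	2	3	Yes	90.3	199	3.13	0.21	7,16,17	1p,19,22	6
RK36	69	F	T3aN2M1	1	3	3	Yes	85.9	23	1.67	0.37	Complex	Complex	Complex
GK101	59	M	T3aN0M0	2	4	3	Yes	89.6	90	3.51	0.67	12	9,14,22	4
GK102	20	F	T1bN0M0	1		3		84.6	132	1.62	1.59	Complex	Complex	Complex
GK116_1	59	M	T1bN0M0	1		3	Yes	93.7	58	5.92	1.02	7,12,17	22	4
GK116_2	59	M	T1bN0M0	1		3		92.0	72	3.35	1.49	2,3,7,12,16,17	21	7
GK116_3	59	M	T1bN0M0	1		3		92.4	55	1.57	1.25	7,12,17	18	4
RK133	68	M	T2aN0M0	2	2	3		90.0	69	2.50	0.59	7,16,17	NA	3
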