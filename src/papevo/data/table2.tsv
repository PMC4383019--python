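chrom	start	ref	alt	mutation_type	sample	gene	dna_change	protein_change
2	178098815	T	G	Non-synonymous SNV	P20	NFE2L2	c.230A>C	p.D77A
2	178098957	G	A	Non-synonymous SNV	RK133	NFE2L2	c.C40T	p.L30F
2	225368499	AT	-	Frameshift deletion	P16	CUL3	c.1246_1247del	p.416_416del
3	47098445	G	A	Stopgain SNV	RK36	SETD2	c.C6829T	p.Q2277X
3	47125708	C	del52bp	Frameshift deletion	P21	SETD2	c.5562insCAAGCCdel58bp	p.P1854fs
3	47142964	G	A	Stopgain SNV	RK36	SETD2	c.C4999T	p.Q1667X
3	47163755	A	G	Non-synonymous SNV	GK116_2	SETD2	c.T2371C	p.S791P
3	47165490	GGCC	-	Frameshift deletion	RK36	SETD2	c.636_639delGGCC	p.V212fs
3	52437911	C	T	Splicing	GK102	BAP1	c.1251-1G>A	splicing
3	52441217	C	T	Non-synonymous SNV	P21	BAP1	c.553G>A	p.G185R
3	52442082	G	-	Frameshift deletion	P02	BAP1	c.267delC	p.N89fs
5	14368959	G	A	Non-synonymous SNV	RK36	TRIO	c.G3017A	p.R1006H
5	14401132	G	A	Non-synonymous SNV	P18	TRIO	c.4675G>A	p.V1559M
5	14488232	T	C	Non-synonymous SNV	RK36	TRIO	c.T7495C	p.S2499P
5	14498309	G	A	Non-synonymous SNV	GK116_3	TRIO	c.G8159A	p.G2720D
7	4839909	-	G	Frameshift insertion	P15	RADIL	c.2875_2876insC	p.P959fs
7	4855034	C	A	Non-synonymous SNV	P11	RADIL	c.2014G>T	p.A672S
7	4855997	G	A	Non-synonymous SNV	P20	RADIL	c.1828C>T	p.R610C
7	91630828	C	G	Non-synonymous SNV	GK101	AKAP9	c.C1597G	p.L533V
7	91631082	-	T	Frameshift insertion	P12	AKAP9	c.1851_1852insT	p.S617fs
7	91712923	A	G	Non-synonymous SNV	P17	AKAP9	c.8576A>G	p.E2859G
7	116339937	G	A	Non-synonymous SNV	RK36	MET	c.G799A	p.E267K
8	144990455	C	T	Non-synonymous SNV	P11	PLEC	c.13438G>A	p.G4480S
8	144992402	G	A	Non-synonymous SNV	P07	PLEC	c.11491C>T	p.R3831W
8	145000007	C	A	Stopgain SNV	P10	PLEC	c.3994G>T	p.E1332X
8	145006606	G	A	Non-synonymous SNV	P13	PLEC	c.1843C>T	p.R615C
10	17089584	-	A	Frameshift insertion	P10	CUBN	c.3158_3159insT	p.T1053fs
10	17110636	C	T	Non-synonymous SNV	RK30	CUBN	c.G2759A	p.G920D
10	17113514	T	C	Non-synonymous SNV	P23	CUBN	c.2536A>G	p.I846V
10	17165680	G	T	Non-synonymous SNV	RK30	CUBN	c.C396A	p.D132E
12	46243511	-	A	Frameshift insertion	P11	ARID2	c.1864_1865insA	p.V622fs
12	46244150	TA	GTAC	Frameshift substitution	P15	ARID2	c.2244_2245GTAC	p.S748fs
12	46287469	A	-	Frameshift deletion	P01	ARID2	c.5328delA	p.L1776fs
13	103388350	C	A	Non-synonymous SNV	P03	CCDC168	c.14697G>T	p.R4899S
13	103395330	C	G	Non-synonymous SNV	GK102	CCDC168	c.G7717C	p.E2573Q
13	103395332	A	-	Frameshift deletion	GK102	CCDC168	c.7715delT	p.I2572fs
13	103395338	A	T	Non-synonymous SNV	GK102	CCDC168	c.T7709A	p.V2570E
13	103400929	TT	-	Frameshift deletion	P10	CCDC168	c.2117_2118del	p.706_706del
16	58554883	CAT	-	Non-frameshift deletion	P06	CNOT1	c.7108_7110del	p.2370_2370del
16	58577328	-	A	Frameshift insertion	P11	CNOT1	c.4617_4618insT	p.C1539fs
16	58610470	A	-	Frameshift deletion	P10	CNOT1	c.1601delT	p.I534fs
17	17117141	-	C	Frameshift insertion	P15	FLCN	c.1568_1569insG	p.K523fs
17	57093106	ATCAA	-	Frameshift deletion	P16	TRIM37	c.2437_2441del	p.813_814del
17	57134346	A	-	Frameshift deletion	P02	TRIM37	c.1089delT	p.F363fs
17	57181680	-	T	Frameshift insertion	P08	TRIM37	c.97_98insA	p.K33fs
17	60028290	A	C	Non-synonymous SNV	GK101	MED13	c.T6187G	p.L2063V
17	60062442	-	T	Frameshift insertion	P10	MED13	c.2395_2396insA	p.K799fs
17	60072560	-	T	Frameshift insertion	P11	MED13	c.2134_2135insA	p.K712fs
19	10597406	C	-	Frameshift deletion	P13	KEAP1	c.1797delG	p.S599fs
19	10602620	G	C	Non-synonymous SNV	RK133	KEAP1	c.C958G	p.R320G
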