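row	protein	species	copies	kd_pm_um	kd_lo_um	kd_hi_um	binds_lipid	censored_above_um	estimated_kd_um	cargo_kd_um	studied	provenance
1	OSH2	yeast	850	1-1.5	1.0	1.5	yes				yes	PLI PMID:11238399; affinity measured, same ref
2	SWH1	yeast	505	3.5-6.2	3.5	6.2	yes				yes	PLI PMID:21119626; affinity measured, same ref
3	KES1	yeast	21166	0.055-2.2	0.055	2.2	yes				yes	PLI PMID:22162133,11916983; affinity measured, same
4	VPS17	yeast	1077	>100			yes	100.0			yes	PLI PMID:11557775; affinity measured, same ref
5	SNX4	yeast	1483	>100			yes	100.0			yes	PLI PMID:11557775; affinity measured, same ref
6	SNX41	yeast	367	>100			yes	100.0			yes	PLI PMID:11557775; affinity measured, same ref
7	VPS5	yeast	1326	>100			yes	100.0			yes	PLI PMID:11557775; affinity measured, same ref
8	ATG20	yeast	519	>100			yes	100.0			yes	PLI PMID:11557775; affinity measured, same ref
9	BOI2	yeast	567	6.6-19.5	6.6	19.5	yes				yes	PLI PMID:15023338; affinity measured, same ref
10	CLA4	yeast	397	20.2-100	20.2	100.0	yes				yes	PLI PMID:15023338; affinity measured, same ref
11	SKM1	yeast	16	3.9-6.4	3.9	6.4	yes				yes	PLI PMID:15023338; affinity measured, same ref
12	BEM1	yeast	1037	>100			yes	100.0			yes	PLI PMID:11557775; affinity measured, same ref
13	BOI1	yeast	399	20	20.0	20.0	yes				yes	PLI PMID:15023338; affinity measured, same ref
14	VAM7	yeast	210	2-3	2.0	3.0	yes				yes	PLI PMID:11557775; affinity measured, same ref
15	SNX3	yeast	5092	2-3	2.0	3.0	yes				yes	PLI PMID:11557775; affinity measured, same ref
16	SLA2	yeast	3904	0.27-3.4	0.27	3.4	yes				yes	PLI PMID:15574875; affinity via homology (AP180) PMID:12740367
17	SYP1	yeast	2467	estimated			yes		0.1;10;100		yes	PLI PMID:19713939,1321812; affinity not known, estimated
18	ENT1	yeast	1750	0.08	0.08	0.08	yes				yes	PLI PMID:22193158,10449404; affinity via homology (EPN1) PMID:17825837
19	ENT2	yeast	1325	0.08	0.08	0.08	yes				yes	PLI PMID:22193158,10449404; affinity via homology (EPN1) PMID:17825837
20	YAP1802	yeast	264	0.27-3.4	0.27	3.4	yes				yes	PLI PMID:22193158,21119626; affinity via homology (AP180) PMID:12740367
0	CHC1	yeast	19278	no binding			no				no	heavy-chain copies; divide by 3 for trimers; not studied
21	SLA1	yeast	2964	no binding			no				yes	scaffold, no lipid binding
22	EDE1	yeast	5964	no binding			no				yes	scaffold, no lipid binding
23	FCHO1	human	3706	estimated			yes		0.1;10;100		yes	PLI PMID:22484487; affinity not known, estimated
24	AP-2	human	244537	2.86 (0.072)	2.86	2.86	yes			0.072	yes	PLI PMID:15916959; affinity measured, same ref; AP2A1 gene; with-cargo value in parentheses
25	EPN1	human	570949	0.08	0.08	0.08	yes				yes	PLI PMID:17825837; affinity measured, same ref
26	PICALM	human	358673	2.7-3.4	2.7	3.4	yes				yes	PLI PMID:25090048; affinity via homology (AP180) PMID:12740367
27	DAB2	human	1078162	0.08	0.08	0.08	yes				yes	PLI PMID:12234931; affinity via homology (EPN1) PMID:17825837
28	FCHO2	human	36302	estimated			yes		0.1;10;100		yes	PLI PMID:20448150; affinity not known, estimated
29	SNAP91/AP180	human	21716	0.27-3.4	0.27	3.4	yes				yes	PLI PMID:12740367; affinity measured, same ref; ppm-scaled copy number
30	LDLRAP1/ARH	human	1048	0.08	0.08	0.08	yes				yes	PLI PMID:12234931; affinity via homology (EPN1) PMID:17825837
31	HIP1	human	13771	0.27-3.4	0.27	3.4	yes				yes	PLI PMID:14732715; affinity via homology (AP180) PMID:12740367
32	HIP1R	human	24161	0.27-3.4	0.27	3.4	yes				yes	PLI PMID:14732715; affinity via homology (AP180) PMID:12740367
33	AMPH	human	89536	0.1	0.1	0.1	yes				yes	PLI PMID:22888025; affinity measured, same ref
34	SH3GL2/Endophilin	human	55621	0.03	0.03	0.03	yes				yes	PLI PMID:22888025; affinity measured, same ref
35	EPS15	human	91354	no binding			no				yes	scaffold, no lipid binding
36	ITSN1	human	20184	no binding			no				yes	scaffold, no lipid binding
37	CLTC	human	1495814	no binding			no				yes	heavy-chain copies; divide by 3 for trimers
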