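outcome	assay_id	protein	rsid	ea	oa	eaf	or	ci_low	ci_high	p	novel
AD	19556_12	CR1	rs679515	T	C	0.183	1.28	1.23	1.33	5.65e-33	No
AD	10816_150	PILRA	rs1859788	A	G	0.304	0.94	0.93	0.96	1.16e-17	No
AD	4992_49	GRN	rs5848	C	T	0.744	0.74	0.68	0.81	2.19e-12	No
AD	8687_26	TMEM106B	rs3173615	C	G	0.598	1.44	1.25	1.66	6.93e-7	No
AD	8465_52	CTSH	rs2289702	C	T	0.894	1.04	1.03	1.06	3.10e-6	No
AD	3285_23	C1R	rs12146727	G	A	0.881	1.11	1.06	1.17	6.41e-6	Yes
AD	8840_61	C1S	rs12146727	G	A	0.881	1.07	1.04	1.10	6.41e-6	Yes
AD	5430_66	SIRPA	rs6136376	A	G	0.640	1.03	1.02	1.04	1.30e-5	Yes
AD	3007_7	SIGLEC9	rs2075803	A	G	0.479	1.03	1.02	1.04	4.30e-5	Yes
AD	6923_1	PLOD2	rs148118826	G	A	0.997	0.59	0.46	0.76	6.18e-5	Yes
AD	8874_53	CLN5	rs700363	G	A	0.910	0.70	0.59	0.84	6.51e-5	Yes
ALS	9294_45	MFAP2	rs3738814	A	G	0.584	0.83	0.75	0.91	5.03e-5	Yes
MS	2654_19	TNFRSF1A	rs1800693	T	C	0.597	0.19	0.13	0.30	1.02e-13	No
MS	10346_5	STAT3	rs4796791	C	T	0.589	0.43	0.35	0.54	1.17e-13	No
MS	16309_30	DKKL1	rs2288481	G	A	0.779	0.13	0.07	0.26	9.33e-10	No
MS	4440_15	FCRL3	rs7528684	G	A	0.416	0.84	0.80	0.89	8.93e-9	No
MS	9468_8	LMAN2	rs4131289	A	G	0.379	2.30	1.61	3.30	4.85e-6	No
MS	3581_53	AHSG	rs4686790	T	G	0.707	0.80	0.73	0.89	2.74e-5	Yes
MS	18172_71	ASF1A	rs4946366	T	C	0.164	0.49	0.34	0.71	1.53e-4	Yes
MS	19556_12	CR1	rs679515	T	C	0.183	1.17	1.08	1.27	1.81e-4	Yes
MS	9870_17	WARS	rs4905957	T	C	0.764	1.32	1.14	1.53	2.21e-4	Yes
MS	13123_3	FLRT3	rs1932953	T	G	0.270	1.09	1.04	1.14	2.60e-4	Yes
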