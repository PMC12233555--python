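outcome	assay_id	protein	rsid	ea	oa	eaf	or	ci_low	ci_high	p	novel
AD	OID30727	APOE	rs8106813	G	A	0.494	0.61	0.57	0.64	3.37e-65	No
AD	OID30697	CR1	rs679515	T	C	0.174	1.26	1.21	1.31	5.65e-33	No
AD	OID20197	PILRB	rs1859788	G	A	0.681	1.07	1.05	1.08	1.16e-17	No
AD	OID21129	PILRA	rs1859788	G	A	0.681	1.08	1.06	1.10	1.16e-17	No
AD	OID20177	CD2AP	rs1385742	A	T	0.355	1.24	1.17	1.32	3.99e-13	No
AD	OID21159	GRN	rs5848	C	T	0.726	0.77	0.72	0.83	2.19e-12	No
AD	OID20763	PRSS8	rs889555	T	C	0.282	0.62	0.53	0.72	1.07e-9	Yes
AD	OID30541	BLNK	rs55769428	A	C	0.962	2.06	1.54	2.74	8.55e-7	No
AD	OID20809	IL34	rs4985556	C	A	0.878	0.95	0.93	0.97	5.65e-6	No
AD	OID30731	C1S	rs12146727	G	A	0.865	1.09	1.05	1.12	6.41e-6	Yes
AD	OID30753	C1R	rs10849546	G	A	0.865	1.13	1.07	1.19	8.55e-6	Yes
AD	OID20304	SIRPA	rs6136377	A	G	0.618	1.03	1.02	1.04	1.37e-5	Yes
AD	OID21472	CD33	rs2455069	G	A	0.427	1.03	1.02	1.05	1.83e-5	No
AD	OID21390	SIGLEC9	rs2075803	A	G	0.447	1.06	1.03	1.10	4.30e-5	Yes
AD	OID21205	ZBTB16	rs73000929	A	G	0.037	1.11	1.05	1.18	1.37e-4	Yes
AD	OID21307	MME	rs79837905	A	G	0.920	1.68	1.26	2.24	4.54e-4	No
PD	OID31141	HIP1R	rs10847864	T	G	0.359	4.01	2.66	6.05	3.64e-11	No
PD	OID20061	CTF1	rs11150601	A	G	0.628	6.84	3.23	14.46	4.92e-7	Yes
ALS	OID20750	TPP1	rs11827437	C	T	0.370	0.72	0.62	0.83	1.61e-5	Yes
ALS	OID20733	TNFSF13	rs3803800	A	G	0.211	0.84	0.77	0.91	3.59e-5	Yes
MS	OID20716	CD58	rs10801908	C	T	0.880	2.30	1.88	2.81	3.54e-16	No
MS	OID21449	CD5	rs4939491	G	A	0.609	0.37	0.29	0.47	4.28e-15	No
MS	OID30519	EVI5	rs11808092	C	A	0.745	0.38	0.30	0.49	4.70e-14	No
MS	OID21155	TNFRSF1A	rs1800693	T	C	0.597	0.12	0.07	0.21	1.02e-13	No
MS	OID20724	CD40	rs4810485	G	T	0.752	0.74	0.68	0.80	1.41e-12	No
MS	OID21313	DKKL1	rs2303759	T	G	0.748	0.91	0.88	0.94	1.89e-10	No
MS	OID21136	IL7R	rs6897932	C	T	0.729	1.13	1.09	1.18	1.84e-9	No
MS	OID20234	TYMP	rs131805	C	T	0.783	0.61	0.52	0.73	2.61e-8	No
MS	OID20496	SLAMF1	rs7535367	G	T	0.861	2.22	1.57	3.13	6.24e-6	No
MS	OID21420	PVALB	rs4821544	T	C	0.697	1.10	1.05	1.15	1.31e-5	Yes
MS	OID20868	TST	rs4821544	T	C	0.697	2.08	1.50	2.89	1.31e-5	Yes
MS	OID21011	PVR	rs2301274	T	C	0.759	0.90	0.86	0.95	2.46e-5	No
MS	OID30423	SPRED2	rs7569084	C	T	0.414	0.39	0.25	0.61	3.76e-5	No
MS	OID20500	PARP1	rs1433574	A	C	0.839	1.70	1.30	2.23	1.04e-4	Yes
MS	OID21005	CDH15	rs11646135	A	G	0.142	1.22	1.10	1.35	1.19e-4	Yes
MS	OID30697	CR1	rs679515	T	C	0.174	1.16	1.07	1.26	1.81e-4	Yes
MS	OID30554	VEGFB	rs660442	A	G	0.200	0.51	0.36	0.73	1.98e-4	Yes
MS	OID21084	WARS	rs12882934	C	A	0.745	1.31	1.14	1.52	2.36e-4	Yes
MS	OID21458	NCS1	rs1054879	A	G	0.508	1.99	1.36	2.92	4.06e-4	Yes
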