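study_id	author	year	ethnicity	cases_hom_risk	cases_het	cases_hom_ref	controls_hom_risk	controls_het	controls_hom_ref	hwe_p_reported
Stacey 2007 Caucasian	Stacey	2007	Caucasian	469	1985	2100	1272	6913	9392	0.999
Stacey 2007 African	Stacey	2007	African	95	211	116	130	222	95	0.990
Stacey 2007 Asian	Stacey	2007	Asian	155	275	122	147	278	132	0.980
Stacey 2007 Mixed	Stacey	2007	Mixed	104	275	183	114	340	259	0.891
He 2014	He	2014	Asian	271	280	72	270	278	72	0.973
Elematore 2014	Elematore	2014	Mixed	62	185	100	100	371	330	0.786
Low 2013	Low	2013	Asian	1801	2705	1016	1496	2739	1254	0.996
Slattery 2011	Slattery	2011	Caucasian	204	755	778	202	862	978	0.550
Udler 2010	Udler	2010	Caucasian	194	942	1041	157	829	1273	0.167
Ruiz-Narvaez 2010	Ruiz-Narvaez	2010	African	188	376	189	214	412	199	0.980
Jiang 2011	Jiang	2011	Asian	233	212	48	232	224	54	0.995
Li 2009	Li	2009	Asian	118	141	32	123	128	40	0.470
Liang 2010	Liang	2010	Asian	486	413	126	455	464	127	0.603
Shan 2012	Shan	2012	Caucasian	147	293	200	78	165	126	0.083
Long 2013	Long	2013	African	328	613	287	563	1027	469	0.988
Kim 2012	Kim	2012	Asian	499	1939	1887	577	1967	1677	0.996
Huo 2012	Huo	2012	African	393	754	362	368	691	324	0.991
Chan 2012	Chan	2012	Asian	541	499	134	629	656	181	0.622
Stevens 2011	Stevens	2011	Caucasian	268	1252	1460	363	1960	2650	0.982
Mulligan 2011	Mulligan	2011	Mixed	585	2652	3109	426	2197	2899	0.730
Han 2011	Han	2011	Asian	1481	1435	369	1361	1617	516	0.317
Long 2010 Asian	Long	2010	Asian	2934	2761	650	1603	1727	465	0.996
Long 2010 Caucasian	Long	2010	Caucasian	258	1172	1330	190	1028	1391	0.997
Latif 2010	Latif	2010	Caucasian	84	395	422	19	137	217	0.660
Barnholtz-Sloan 2010 African	Barnholtz-Sloan	2010	African	196	378	166	182	333	142	0.654
Barnholtz-Sloan 2010 Caucasian	Barnholtz-Sloan	2010	Caucasian	133	512	585	89	440	589	0.591
Gorodnova 2010	Gorodnova	2010	Caucasian	16	50	74	15	82	77	0.294
Hemminki 2010	Hemminki	2010	Caucasian	154	626	635	124	704	1002	0.982
Mcinerney 2009	Mcinerney	2009	Caucasian	82	382	486	58	396	532	0.161
Antoniou 2008	Antoniou	2008	Caucasian	497	2173	2422	382	1831	2244	0.756
Tapper 2008	Tapper	2008	Caucasian	76	371	452	196	1137	1647	0.990
Campa 2011	Campa	2011	Mixed	1071	3528	3706	1150	4724	5721	0.001
Garcia-Closas 2008	Garcia-Closas	2008	Mixed	1848	7132	7759	2026	9705	13295	<0.0001
Barzan 2013 Asian	Barzan	2013	Asian	482	413	89	961	990	255	0.999
Barzan 2013 Caucasian	Barzan	2013	Caucasian	36	140	135	65	369	526	0.979
Rinella 2013	Rinella	2013	Caucasian	131	335	214	106	366	315	0.985
Zheng 2009	Zheng	2009	African	222	404	184	482	891	411	0.984
Butt 2012	Butt	2012	Caucasian	64	278	353	95	512	780	0.380
Mizoo 2013	Mizoo	2013	Asian	160	230	74	142	227	91	0.987
Harlid 2012	Harlid	2012	Caucasian	330	1420	1794	352	1898	2768	0.280
Zheng 2010	Zheng	2010	Asian	1401	1325	313	1286	1410	386	0.987
Tamimi 2010	Tamimi	2010	Caucasian	54	300	333	50	273	415	0.576
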