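study_id	author	year	ethnicity	cases_hom_risk	cases_het	cases_hom_ref	controls_hom_risk	controls_het	controls_hom_ref	hwe_p_reported
He 2014	He	2014	Asian	25	199	399	18	175	427	0.989
Udler 2010	Udler	2010	Caucasian	455	1089	611	425	1067	736	0.274
Li 2009	Li	2009	Asian	15	82	198	9	90	209	0.854
Liang 2010	Liang	2010	Asian	48	314	670	47	309	708	0.078
Shan 2012	Shan	2012	Caucasian	138	289	208	46	176	146	0.529
Long 2010 Asian	Long	2010	Asian	246	1971	3941	118	1080	2460	0.968
Long 2010 Caucasian	Long	2010	Caucasian	336	788	463	279	709	451	0.991
Barnholtz-Sloan 2010 African	Barnholtz-Sloan	2010	African	87	342	313	59	304	295	0.121
Barnholtz-Sloan 2010 Caucasian	Barnholtz-Sloan	2010	Caucasian	257	587	386	201	559	358	0.501
Barzan 2013 Asian	Barzan	2013	Asian	43	327	614	72	651	1483	0.957
Barzan 2013 Caucasian	Barzan	2013	Caucasian	81	155	75	186	473	301	0.994
Zheng 2009	Zheng	2009	African	80	349	381	170	762	852	0.984
Butt 2012	Butt	2012	Caucasian	149	338	192	272	637	443	0.119
Zheng 2010	Zheng	2010	Asian	118	961	1960	96	898	2088	0.963
Tamimi 2010	Tamimi	2010	Caucasian	132	359	194	135	380	220	0.193
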