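study_id	author	year	ethnicity	cases_hom_risk	cases_het	cases_hom_ref	controls_hom_risk	controls_het	controls_hom_ref	hwe_p_reported
He 2014	He	2014	Asian	110	304	209	115	304	201	0.809
Udler 2010	Udler	2010	Caucasian	527	1111	546	497	1099	681	0.176
Jiang 2011	Jiang	2011	Asian	170	239	84	162	251	97	0.990
Li 2009	Li	2009	Asian	106	138	54	97	141	55	0.766
Liang 2010	Liang	2010	Asian	347	507	186	338	519	204	0.850
Shan 2012	Shan	2012	Caucasian	190	301	147	98	180	85	0.894
Chan 2012	Chan	2012	Asian	404	573	198	532	669	262	0.419
Long 2010 Asian	Long	2010	Asian	546	1448	960	554	1469	974	0.998
Long 2010 Caucasian	Long	2010	Caucasian	286	573	286	274	571	297	0.989
Barnholtz-Sloan 2010 African	Barnholtz-Sloan	2010	African	164	370	208	165	329	164	0.999
Barnholtz-Sloan 2010 Caucasian	Barnholtz-Sloan	2010	Caucasian	337	580	313	242	574	302	0.319
Zheng 2009	Zheng	2009	African	189	405	216	423	891	470	0.986
Butt 2012	Butt	2012	Caucasian	165	338	195	275	657	451	0.203
Zheng 2010	Zheng	2010	Asian	1001	1486	552	1008	1509	565	0.995
Tamimi 2010	Tamimi	2010	Caucasian	151	337	193	130	366	241	0.659
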