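snp	cfa	cfa_pos	vvu	vvu_pos	freq_diff	p_adj	cluster
S1_285236887	12	18837258	1	167384431	0.80	1.36E-08	1
S1_285704585	12	19304956	1	167852129	0.82	9.59E-07	1
S1_812259209	2	51452767	2	138634343	0.80	3.76E-08
S1_1648737836	36	1743329	3	1743329	0.79	1.08E-07
S1_1673084403	36	26089896	3	26089896	0.77	1.74E-07
S1_1964707411	6	54892000	3	127827426	0.75	2.05E-07
S1_1977727319	6	67911908	3	140847334	0.82	1.28E-08	2
S1_1977727423	6	67912012	3	140847438	0.97	3.58E-13	2
S1_1977727436	6	67912025	3	140847451	0.82	1.28E-08	2
S1_1531784156	32	23626827	4	42200559	0.88	2.20E-07
S1_1794484892	4	61861562	4	127688948	0.86	1.16E-08
S1_1712828536	38	4119843	5	105433843	0.82	4.94E-09
S1_986356551	22	31130422	6	31130422	0.77	6.91E-07	3
S1_987024936	22	31798807	6	31798807	0.75	8.95E-07	3
S2_113588644	8	32614012	6	94053946	0.80	3.76E-08	4
S2_113588820	8	32614188	6	94054122	0.80	3.76E-08	4
S2_148636413	8	67661781	6	129101715	0.75	8.95E-07
S1_540429371	16	13131693	7	13131693	0.7750	9.22E-08
S1_449099782	14	46959949	7	106592795	1.0000	2.05E-07	5
S1_449883141	14	47743308	7	107376154	0.7500	9.48E-07	5
S1_1235603545	27	28350100	8	28350100	0.8417	1.05E-08	6
S1_1235712667	27	28459222	8	28459222	0.8973	1.52E-07	6
S1_1236925680	27	29672235	8	29672235	0.7500	8.95E-07	6
S1_1238406667	27	31153222	8	31153222	0.7750	5.42E-08	6
S1_1240026884	27	32773439	8	32773439	0.8000	3.09E-08	6
S1_1240026888	27	32773443	8	32773443	0.8250	4.94E-09	6
S1_1240026889	27	32773444	8	32773444	0.8250	4.94E-09	6
S1_1240026890	27	32773445	8	32773445	0.8250	4.94E-09	6
S1_1240254310	27	33000865	8	33000865	0.8000	2.20E-08	6
S1_1240254354	27	33000909	8	33000909	0.8000	2.20E-08	6
S1_1240725455	27	33472010	8	33472010	0.8184	1.81E-08	6
S1_1240725498	27	33472053	8	33472053	0.8184	1.81E-08	6
S1_1240736757	27	33483312	8	33483312	0.8711	6.52E-10	6
S1_1242777422	27	35523977	8	35523977	0.8591	1.34E-08	7
S1_1242825122	27	35571677	8	35571677	0.8000	3.09E-08	7
S1_1243526396	27	36272951	8	36272951	0.9118	5.75E-09	7
S1_1243526433	27	36272988	8	36272988	0.9118	5.75E-09	7
S1_1243639565	27	36386120	8	36386120	0.8000	4.02E-08	7
S1_1243639695	27	36386250	8	36386250	0.7500	7.52E-07	7
S1_1246055552	27	38802107	8	38802107	0.8000	3.76E-08
S1_1252424198	27	45170753	8	45170753	0.7750	1.97E-07
S1_648198405	17	61267781	8	48897988	0.8733	8.80E-07
S1_644111987	17	57181363	8	52984406	0.8000	2.20E-08
S1_641943154	17	55012530	8	55153239	0.8250	2.08E-08
S1_625871222	17	38940598	8	71225171	0.8500	7.10E-10
S1_619211128	17	32280504	8	77885265	0.7500	8.95E-07	8
S1_618721739	17	31791115	8	78374654	0.9063	2.22E-09	8
S1_618399870	17	31469246	8	78696523	0.7750	5.42E-08	8
S1_616717168	17	29786544	8	80379225	0.8404	9.78E-08	8
S1_922966764	21	18599358	11	32259265	0.8125	7.05E-07	9
S1_922966746	21	18599340	11	32259283	0.8125	7.05E-07	9
S1_1038102049	23	21435886	11	72294509	0.8000	2.20E-08	10
S1_1039257018	23	22590855	11	73449478	0.8000	8.32E-07	10
S1_1039763208	23	23097045	11	73955668	1.0000	3.49E-09	10
S1_237429054	11	45418622	12	28970475	0.8111	5.07E-08
S1_201401022	11	9390590	12	64998507	0.7500	3.64E-07
S1_1379515115	3	43357310	14	91056089	0.8750	3.16E-08	11
S1_1379640157	3	43482352	14	91181131	0.8421	1.98E-09	11
S1_1380118429	3	43960624	14	91659403	0.8500	7.10E-10	11
S1_1380118781	3	43960976	14	91659755	0.8500	7.10E-10	11
S1_1380128532	3	43970727	14	91669506	0.8250	3.20E-09	11
S1_1380128533	3	43970728	14	91669507	0.8500	7.10E-10	11
S1_1380128577	3	43970772	14	91669551	0.8500	7.10E-10	11
S1_1380216459	3	44058654	14	91757433	0.8000	8.43E-08	11
S1_1380788560	3	44630755	14	92329534	0.8889	7.45E-07	11
S1_1380790456	3	44632651	14	92331430	0.8824	1.64E-09	11
S1_1384636870	3	48479065	14	96177844	0.8250	3.20E-09
S1_1272088483	28	18958228	15	99068409	0.7921	8.52E-08
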