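number	chrom	strand	start	end	length_bp	coverage_pct	range_bin	qgap_pct	indel	context
1	chr11	-	97063674	97072831	9158	84.70%	[80%-90%)	3.28%	NA	intergenic
2	chr19	-	23582963	23597406	14444	81.45%	[80%-90%)	5.78%	Insertion	intergenic
3	chr17	+	28556159	28565079	8921	81.22%	[80%-90%)	9.29%	NA	intergenic
4	chr1	+	156345936	156354251	8316	76.67%	[70%-80%)	12.10%	Deletion	intergenic
5	chr9	+	31695596	31703805	8210	76.57%	[70%-80%)	2.80%	NA	intergenic
6	chr5	-	52655093	52662923	7831	73.29%	[70%-80%)	4.76%	NA	intergenic
7	chr19	-	25615095	25622844	7750	71.85%	[70%-80%)	6.43%	NA	intergenic
8	chr12	-	51714625	51722440	7816	70.94%	[70%-80%)	7.63%	NA	intergenic
9	chr6	-	73941843	73949302	7460	70.49%	[70%-80%)	4.11%	NA	intergenic
10	chr9	-	84591713	84599232	7520	69.51%	[60%-70%)	24.21%	Deletion	intron
11	chr3	+	79615035	79622061	7027	64.57%	[60%-70%)	17.82%	Deletion	intron
12	chrX	+	56602551	56609242	6692	63.26%	[60%-70%)	4.37%	NA	intergenic
13	chr1	-	135696367	135712562	16196	61.48%	[60%-70%)	6.97%	Insertion	intron
14	chr11	+	63656712	63663509	6798	59.90%	[50%-60%)	31.36%	Deletion	intergenic
15	chr2A	+	64123614	64129736	6123	57.81%	[50%-60%)	20.10%	Deletion	intron
16	chr3	-	128565266	128571536	6271	57.64%	[50%-60%)	25.16%	Deletion	intron
17	chr12	-	81696811	81702819	6009	56.24%	[50%-60%)	13.24%	Deletion	intergenic
18	chr11	+	49590235	49596119	5885	54.38%	[50%-60%)	5.42%	NA	intergenic
19	chr10	-	98677603	98683109	5507	50.71%	[50%-60%)	37.81%	Deletion	genic &intergenic
20	chr1	+	108430301	108435591	5291	49.26%	[40%-50%)	32.31%	Deletion	intergenic
21	chrY	+	23381750	23386956	5207	48.45%	[40%-50%)	31.40%	Deletion	intergenic
22	chr11	+	50352478	50357771	5294	48.21%	[40%-50%)	9.03%	NA	intergenic
23	chr11	-	49637737	49642530	4794	43.57%	[40%-50%)	35.29%	Deletion	intergenic
24	chr4	+	137449286	137454131	4846	42.39%	[40%-50%)	45.12%	Deletion	intergenic
25	chr12	+	102968149	102972730	4582	42.14%	[40%-50%)	8.05%	NA	intergenic
26	chr3	+	109740319	109744759	4441	41.74%	[40%-50%)	30.22%	Deletion	intergenic
27	chr11	-	14869711	14874159	4449	41.19%	[40%-50%)	26.33%	Deletion	intergenic
28	chr4	+	64843173	64847502	4330	40.68%	[40%-50%)	3.57%	NA	intergenic
29	chrX	+	34789238	34793597	4360	40.26%	[40%-50%)	24.69%	Deletion	intergenic
30	chr8	+	44511870	44516437	4568	40.01%	[40%-50%)	7.33%	NA	intergenic
31	chr6	-	155777868	155781847	3980	37.49%	[30%-40%)	1.50%	NA	exonic&intronic
32	chr19	+	24073629	24078094	4466	36.96%	[30%-40%)	4.79%	NA	intergenic
33	chr4	-	77803811	77807756	3946	36.44%	[30%-40%)	34.61%	Deletion	intergenic
34	chr8	-	12333790	12337817	4028	36.18%	[30%-40%)	27.03%	Deletion	intron
35	chr7	+	6075204	6079128	3925	35.29%	[30%-40%)	28.35%	Deletion	intron
36	chr8	+	43749874	43753733	3860	34.71%	[30%-40%)	38.35%	Deletion	intergenic
37	chrY	+	6360429	6370254	9826	34.32%	[30%-40%)	38.19%	Insertion,Deletion	intergenic
38	chr8	-	86619640	86623356	3717	34.09%	[30%-40%)	34.77%	Deletion	intergenic
39	chr20	+	29240803	29250628	9826	34.03%	[30%-40%)	38.72%	Insertion,Deletion	intergenic
40	chr4	+	77195305	77198763	3459	32.47%	[30%-40%)	4.25%	NA	intergenic
41	chr2A	+	102337670	102341003	3334	31.08%	[30%-40%)	11.22%	Deletion	intergenic
42	chr5	+	150548523	150551566	3044	28.84%	[20%-30%)	28.68%	Deletion	intron
43	chr7	+	50863865	50867270	3406	27.87%	[20%-30%)	28.99%	Deletion	intergenic
44	chr1	+	45743923	45746943	3021	27.13%	[20%-30%)	10.68%	Deletion	intergenic
45	chrX	+	41627863	41630750	2888	26.01%	[20%-30%)	13.10%	Deletion	intron
46	chrX	-	42154219	42156882	2664	24.40%	[20%-30%)	13.70%	Deletion	intergenic
47	chr22	-	1446161	1448721	2561	23.70%	[20%-30%)	1.58%	NA	intron
48	chr16	-	44723847	44726410	2564	23.53%	[20%-30%)	11.83%	Deletion	intergenic
49	chrY	-	3095532	3098114	2583	23.20%	[20%-30%)	14.79%	Deletion	intergenic
50	chrY	+	13438427	13440964	2538	23.15%	[20%-30%)	13.88%	Deletion	intergenic
51	chr19	-	20847619	20850034	2416	22.88%	[20%-30%)	2.80%	NA	intergenic
52	chr8	-	11324731	11327317	2587	22.77%	[20%-30%)	15.32%	Deletion	intergenic
53	chr1	+	31825639	31827932	2294	21.66%	[20%-30%)	44.57%	Deletion	intergenic
54	chr2B	-	5807936	5810201	2266	21.54%	[20%-30%)	5.44%	NA	intergenic
55	chr4	+	49398166	49400489	2324	21.00%	[20%-30%)	14.29%	Deletion	intergenic
56	chr15	-	19096168	19099630	3463	20.90%	[20%-30%)	21.64%	Insertion,Deletion	genic&intergenic
57	chr4	+	162706670	162708848	2179	20.70%	[20%-30%)	5.49%	NA	intergenic
58	chr2B	+	100074966	100077139	2174	20.56%	[20%-30%)	5.31%	NA	intron
59	chr18	-	44459897	44461968	2072	19.48%	[10%-20%)	0.54%	NA	intergenic
60	chr19	+	25500990	25503068	2079	19.47%	[10%-20%)	2.58%	NA	intergenic
61	chr14	+	71784651	71786596	1946	18.45%	[10%-20%)	8.25%	NA	intron
62	chr4	+	55246241	55248103	1863	17.68%	[10%-20%)	10.87%	Deletion	intergenic
63	chr6	+	58293089	58294835	1747	16.57%	[10%-20%)	0.63%	NA	intergenic
64	chr13	-	59301174	59302916	1743	16.29%	[10%-20%)	6.77%	NA	intergenic
65	chr11	-	49783110	49784802	1693	15.89%	[10%-20%)	2.00%	NA	intergenic
66	chr2A	-	77283713	77285331	1619	15.17%	[10%-20%)	1.55%	NA	intron
67	chr2B	-	97034956	97036587	1632	15.12%	[10%-20%)	14.74%	Deletion	intergenic
68	chr5_NW_019932883v1_random	-	1485086	1486708	1623	14.83%	[10%-20%)	17.16%	Deletion	intergenic
69	chr4	-	50892584	50893971	1388	12.91%	[10%-20%)	15.64%	Deletion	intron
70	chrY	-	14091617	14092838	1222	11.28%	[10%-20%)	4.13%	NA	intergenic
71	chrY	-	5451943	5453164	1222	11.28%	[10%-20%)	4.13%	NA	intergenic
72	chrX	-	46463406	46464551	1146	10.90%	[10%-20%)	16.33%	Deletion	intergenic
73	chrY	-	1087726	1088806	1081	10.28%	[10%-20%)	0.83%	NA	intergenic
74	chr5	-	32949251	32950412	1162	9.90%	[0%-10%)	11.51%	Deletion	intergenic
75	chr10	-	77164804	77165954	1151	9.65%	[0%-10%)	13.06%	Deletion	intergenic
76	chr1	+	104828192	104829066	875	8.14%	[0%-10%)	2.18%	NA	intergenic
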