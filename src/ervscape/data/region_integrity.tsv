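number	locus	ltr5_pct	gag_pct	pro_pct	pol_pct	env_pct	ltr3_pct
1	chr11 97063674 97072831	48.66%	99.67%	100.00%	99.71%	99.40%	40.36%
2	chr19 23582963 23597406	38.86%	99.43%	99.40%	97.66%	98.15%	37.12%
3	chr17 28556159 28565079	66.11%	99.29%	98.71%	97.25%	90.89%	32.86%
4	chr1 156345936 156354251	50.08%	72.83%	65.77%	95.20%	99.57%	36.41%
5	chr9 31695596 31703805	80.81%	99.72%	99.70%	99.67%	67.48%	0.00%
6	chr5 52655093 52662923	0.00%	92.79%	98.91%	99.45%	90.89%	30.65%
7	chr19 25615095 25622844	0.00%	93.22%	100.00%	97.07%	90.81%	28.99%
8	chr12 51714625 51722440	0.00%	93.12%	99.80%	99.74%	91.07%	28.99%
9	chr6 73941843 73949302	0.00%	85.44%	99.90%	99.60%	90.68%	15.01%
10	chr9 84591713 84599232	75.20%	99.67%	99.30%	30.92%	99.27%	36.97%
11	chr3 79615035 79622061	0.00%	93.65%	98.31%	65.97%	90.42%	41.47%
12	chrX 56602551 56609242	0.00%	91.80%	99.00%	99.16%	61.04%	0.00%
13	chr1 135696367 135712562	0.00%	36.65%	96.02%	99.23%	89.52%	35.23%
14	chr11 63656712 63663509	75.91%	70.22%	0.00%	57.33%	99.31%	9.64%
15	chr2A 64123614 64129736	0.00%	69.27%	77.51%	62.97%	90.51%	32.86%
16	chr3 128565266 128571536	0.00%	93.84%	51.14%	57.99%	91.19%	30.65%
17	chr12 81696811 81702819	0.00%	77.15%	56.02%	99.82%	54.90%	0.00%
18	chr11 49590235 49596119	0.00%	49.88%	99.90%	99.56%	59.66%	0.00%
19	chr10 98677603 98683109	50.00%	99.62%	25.97%	10.07%	98.71%	0.00%
20	chr1 108430301 108435591	76.54%	99.29%	98.81%	17.11%	39.65%	0.00%
21	chrY 23381750 23386956	0.00%	86.58%	78.61%	24.21%	95.83%	0.00%
22	chr11 50352478 50357771	0.00%	0.00%	14.93%	99.34%	90.64%	38.47%
23	chr11 49637737 49642530	0.00%	51.07%	99.80%	41.17%	65.42%	22.20%
24	chr4 137449286 137454131	33.49%	75.30%	0.00%	14.91%	88.53%	0.00%
25	chr12 102968149 102972730	0.00%	0.00%	0.00%	78.46%	91.15%	35.70%
26	chr3 109740319 109744759	0.00%	0.52%	82.19%	36.52%	99.70%	37.20%
27	chr11 14869711 14874159	0.00%	0.00%	33.33%	63.85%	91.07%	33.10%
28	chr4 64843173 64847502	0.00%	0.00%	0.00%	70.18%	99.61%	18.01%
29	chrX 34789238 34793597	0.00%	0.00%	16.02%	64.10%	90.85%	40.28%
30	chr8 44511870 44516437	14.14%	90.04%	99.60%	48.39%	0.00%	0.00%
31	chr6 155777868 155781847	0.00%	0.00%	0.00%	92.89%	67.65%	0.00%
32	chr19 24073629 24078094	0.00%	82.12%	99.80%	56.92%	0.00%	0.00%
33	chr4 77803811 77807756	0.00%	0.00%	55.72%	41.87%	90.46%	24.41%
34	chr8 12333790 12337817	0.00%	0.00%	0.00%	61.68%	90.59%	28.83%
35	chr7 6075204 6079128	0.00%	0.00%	0.00%	59.12%	90.94%	26.15%
36	chr8 43749874 43753733	0.00%	0.00%	34.03%	41.47%	90.34%	35.55%
37	chrY 6360429 6370254	0.00%	0.00%	34.03%	41.98%	89.99%	28.99%
38	chr8 86619640 86623356	0.00%	0.00%	3.28%	62.45%	70.75%	35.70%
39	chr20 29240803 29250628	0.00%	0.00%	34.03%	41.98%	89.99%	28.99%
40	chr4 77195305 77198763	0.00%	0.00%	0.00%	45.75%	99.01%	3.40%
41	chr2A 102337670 102341003	0.00%	0.00%	0.00%	37.29%	90.59%	27.33%
42	chr5 150548523 150551566	0.00%	0.00%	19.20%	63.77%	55.67%	0.00%
43	chr7 50863865 50867270	0.00%	0.00%	7.06%	64.03%	55.93%	0.00%
44	chr1 45743923 45746943	45.26%	99.43%	37.61%	0.00%	0.00%	0.00%
45	chrX 41627863 41630750	0.00%	0.00%	0.00%	17.62%	90.72%	33.81%
46	chrX 42154219 42156882	0.00%	0.00%	0.00%	6.96%	90.46%	38.63%
47	chr22 1446161 1448721	0.00%	86.39%	88.06%	0.00%	0.00%	0.00%
48	chr16 44723847 44726410	0.00%	0.00%	0.00%	5.13%	90.21%	35.86%
49	chrY 3095532 3098114	0.00%	0.00%	0.00%	6.59%	90.89%	33.18%
50	chrY 13438427 13440964	0.00%	0.00%	0.00%	6.92%	90.51%	29.62%
51	chr19 20847619 20850034	0.00%	37.55%	99.90%	31.21%	0.00%	0.00%
52	chr8 11324731 11327317	0.00%	0.00%	0.00%	8.86%	91.02%	28.75%
53	chr1 31825639 31827932	0.00%	0.00%	34.03%	42.01%	42.53%	0.00%
54	chr2B 5807936 5810201	0.00%	0.00%	0.00%	0.00%	77.15%	36.89%
55	chr4 49398166 49400489	0.00%	0.00%	0.00%	0.00%	80.37%	35.15%
56	chr15 19096168 19099630	0.00%	0.00%	0.00%	2.67%	82.04%	32.62%
57	chr4 162706670 162708848	0.00%	0.00%	0.00%	0.00%	77.32%	29.70%
58	chr2B 100074966 100077139	0.00%	0.00%	0.00%	0.00%	87.84%	9.95%
59	chr18 44459897 44461968	0.00%	0.00%	0.00%	0.00%	84.75%	6.32%
60	chr19 25500990 25503068	0.00%	84.87%	47.56%	0.00%	0.00%	0.00%
61	chr14 71784651 71786596	0.00%	0.00%	0.00%	0.00%	61.25%	40.84%
62	chr4 55246241 55248103	0.00%	0.00%	33.93%	57.33%	0.00%	0.00%
63	chr6 58293089 58294835	0.00%	5.22%	91.84%	31.61%	0.00%	0.00%
64	chr13 59301174 59302916	0.00%	0.00%	0.00%	0.00%	53.91%	37.28%
65	chr11 49783110 49784802	0.00%	0.00%	0.00%	61.94%	0.09%	0.00%
66	chr2A 77283713 77285331	0.00%	76.72%	0.00%	0.00%	0.00%	0.00%
67	chr2B 97034956 97036587	0.00%	0.00%	0.00%	0.00%	54.17%	28.83%
68	chr5_NW_019932883v1_random 1485086 1486708	48.97%	39.26%	0.00%	0.00%	0.00%	0.00%
69	chr4 50892584 50893971	0.00%	0.00%	0.00%	0.00%	54.25%	9.56%
70	chrY 14091617 14092838	0.00%	0.00%	0.00%	0.00%	41.92%	19.04%
71	chrY 5451943 5453164	0.00%	0.00%	0.00%	0.00%	41.92%	19.04%
72	chrX 46463406 46464551	0.00%	0.00%	34.03%	30.99%	0.00%	0.00%
73	chrY 1087726 1088806	0.00%	0.00%	0.00%	0.00%	41.92%	8.06%
74	chr5 32949251 32950412	0.00%	0.00%	0.00%	0.00%	30.03%	35.70%
75	chr10 77164804 77165954	0.00%	0.00%	0.00%	0.00%	26.63%	39.89%
76	chr1 104828192 104829066	0.00%	0.00%	0.00%	25.68%	13.57%	0.00%
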