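number	locus	gag_div	pro_div	pol_div	env_div	mean_div	t_formula	age_myr
1	chr11 97063674 97072831	0.113	0.087	0.086	0.076	0.091	0.4525	45.25
2	chr19 23582963 23597406	0.109	0.075	0.096	0.087	0.092	0.45875	45.875
3	chr17 28556159 28565079	0.064	0.062	0.077	0.054	0.064	0.32125	32.125
4	chr1 156345936 156354251	NA	NA	0.092	0.070	0.081	0.405	40.5
5	chr9 31695596 31703805	0.124	0.089	0.101	NA	0.105	0.523333333	52.33333333
6	chr5 52655093 52662923	0.100	0.050	0.029	0.054	0.058	0.29125	29.125
7	chr19 25615095 25622844	0.099	0.071	0.039	0.068	0.069	0.34625	34.625
8	chr12 51714625 51722440	0.129	0.080	0.052	0.063	0.081	0.405	40.5
9	chr6 73941843 73949302	NA	0.050	0.075	0.054	0.060	0.298333333	29.83333333
10	chr9 84591713 84599232	0.109	0.091	NA	0.074	0.091	0.456666667	45.66666667
11	chr3 79615035 79622061	0.048	0.054	NA	0.047	0.050	0.248333333	24.83333333
12	chrX 56602551 56609242	0.068	0.059	0.065	NA	0.064	0.32	32
13	chr1 135696367 135712562	NA	0.071	0.044	NA	0.058	0.2875	28.75
14	chr11 63656712 63663509	NA	NA	NA	0.075	0.075	0.375	37.5
15	chr2A 64123614 64129736	NA	NA	NA	0.045	0.045	0.225	22.5
16	chr3 128565266 128571536	0.088	NA	NA	0.043	0.066	0.3275	32.75
17	chr12 81696811 81702819	NA	NA	0.041	NA	0.041	0.205	20.5
18	chr11 49590235 49596119	NA	0.082	0.085	NA	0.084	0.4175	41.75
19	chr10 98677603 98683109	0.099	NA	NA	0.069	0.084	0.42	42
20	chr1 108430301 108435591	0.107	0.078	NA	NA	0.093	0.4625	46.25
21	chrY 23381750 23386956	NA	NA	NA	0.098	0.098	0.49	49
22	chr11 50352478 50357771	NA	NA	0.078	0.065	0.072	0.3575	35.75
23	chr11 49637737 49642530	NA	0.085	NA	NA	0.085	0.425	42.5
25	chr12 102968149 102972730	NA	NA	NA	0.031	0.031	0.155	15.5
26	chr3 109740319 109744759	NA	NA	NA	0.078	0.078	0.39	39
27	chr11 14869711 14874159	NA	NA	NA	0.049	0.049	0.245	24.5
28	chr4 64843173 64847502	NA	NA	NA	0.062	0.062	0.31	31
29	chrX 34789238 34793597	NA	NA	NA	0.040	0.040	0.2	20
30	chr8 44511870 44516437	0.105	0.075	NA	NA	0.090	0.45	45
31	chr6 155777868 155781847	NA	NA	0.093	NA	0.093	0.465	46.5
32	chr19 24073629 24078094	NA	0.076	NA	NA	0.076	0.38	38
33	chr4 77803811 77807756	NA	NA	NA	0.075	0.075	0.375	37.5
34	chr8 12333790 12337817	NA	NA	NA	0.065	0.065	0.325	32.5
35	chr7 6075204 6079128	NA	NA	NA	0.066	0.066	0.33	33
36	chr8 43749874 43753733	NA	NA	NA	0.087	0.087	0.435	43.5
40	chr4 77195305 77198763	NA	NA	NA	0.084	0.084	0.42	42
41	chr2A 102337670 102341003	NA	NA	NA	0.030	0.030	0.15	15
44	chr1 45743923 45746943	0.083	NA	NA	NA	0.083	0.415	41.5
45	chrX 41627863 41630750	NA	NA	NA	0.074	0.074	0.37	37
46	chrX 42154219 42156882	NA	NA	NA	0.046	0.046	0.23	23
48	chr16 44723847 44726410	NA	NA	NA	0.054	0.054	0.27	27
49	chrY 3095532 3098114	NA	NA	NA	0.090	0.090	0.45	45
50	chrY 13438427 13440964	NA	NA	NA	0.095	0.095	0.475	47.5
51	chr19 20847619 20850034	NA	0.091	NA	NA	0.091	0.455	45.5
52	chr8 11324731 11327317	NA	NA	NA	0.068	0.068	0.34	34
63	chr6 58293089 58294835	NA	0.068	NA	NA	0.068	0.34	34
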