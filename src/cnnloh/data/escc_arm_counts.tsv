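unit_id	loss	neutral	gain
1p	2930	6522	1124
1q	459	7674	233
2p	371	10770	180
2q	3015	18939	1161
3p	15335	12064	194
3q	41	4168	3047
4p	4771	7452	0
4q	9142	17905	1958
5p	0	1259	56
5q	7744	8777	16
6p	342	4870	410
6q	165	2773	427
7p	9	5491	1889
7q	151	6452	1398
8p	1580	6234	989
8q	47	4633	12641
9p	2772	13333	2187
9q	1965	27212	2223
10p	472	2063	204
10q	1728	12075	848
11p	2367	6902	122
11q	5116	10422	1839
12p	156	3251	1822
12q	67	5980	747
13q	5897	25964	3787
14q	1484	7446	2001
15q	685	8313	1196
16p	111	1284	0
16q	1	2832	294
17p	324	6939	456
17q	38	14754	1536
18p	488	1147	961
18q	3108	6838	32
19p	1	1065	3
19q	932	2482	91
20p	0	229	1049
20q	60	1677	36
21q	3825	5599	20
22q	621	3274	222
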