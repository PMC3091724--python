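unit_id	loss	neutral	gain
1	2260	26801	2747
2	0	205	163
3	0	139	238
4	2093	27655	6427
5	0	0	24
6	210	12661	1880
7	0	2905	654
8	4	2217	187
9	1	266	326
10	1075	12087	4384
11	3678	67726	6755
12	0	0	41
13	209	5154	750
14	4084	9190	224
15	0	3	0
16	0	54	1377
17	5732	10842	360
18	0	1553	554
19	0	0	0
20	0	137	390
21	62	16332	3560
22	4410	6357	413
23	5939	5953	2631
24	5672	9354	747
25	20	17114	5871
26	21495	15229	967
27	4500	6299	1321
28	0	37	457
29	444	15400	2378
30	16432	25394	673
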