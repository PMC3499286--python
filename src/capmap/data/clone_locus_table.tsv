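chromosome	fwd_clones	fwd_clones_duroc	fwd_loci	fwd_loci_duroc	rev_clones	rev_clones_duroc	rev_loci	rev_loci_duroc	total_clones	total_clones_duroc	total_loci	total_loci_duroc
1	1128	164	560	134	1197	133	594	112	2325	297	1154	246
2	1144	138	564	123	1180	161	563	134	2324	299	1127	257
3	744	97	380	87	871	121	468	99	1615	218	848	186
4	748	88	366	71	793	96	385	81	1541	184	751	152
5	710	86	310	63	685	77	313	65	1395	163	623	128
6	1184	174	552	133	1040	130	539	115	2224	304	1091	248
7	1013	117	437	98	1118	125	397	97	2131	242	834	195
8	563	69	267	58	393	50	209	44	956	119	476	102
9	699	94	339	72	673	85	339	75	1372	179	678	147
10	409	48	167	37	362	37	169	32	771	85	336	69
11	225	26	119	25	237	22	129	20	462	48	248	45
12	723	89	334	76	667	68	328	60	1390	157	662	136
13	922	124	431	101	890	93	467	80	1812	217	898	181
14	894	101	405	80	920	116	424	90	1814	217	829	170
15	568	79	281	64	518	61	247	55	1086	140	528	119
16	266	35	137	26	252	39	123	35	518	74	260	61
17	607	70	212	59	365	47	190	38	972	117	402	97
18	325	32	144	29	354	38	151	30	679	70	295	59
X	364	56	195	49	402	73	203	55	766	129	398	104
Y	5	0	2	0	1	0	1	0	6	0	3	0
Unplaced scaffolds	1854	308	747	156	1417	162	706	135	3271	470	1453	291
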