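chromosome	fwd_contigs	fwd_singlets	fwd_loci	rev_contigs	rev_singlets	rev_loci	total_contigs	total_singlets	total_loci
1	580	3343	1799	594	3346	1798	1174	6689	3597
2	639	2983	1452	646	2855	1365	1285	5838	2817
3	415	2248	1132	472	2574	1299	887	4822	2431
4	435	2049	1013	398	2112	1025	833	4161	2038
5	373	1774	870	375	2007	846	748	3781	1716
6	667	3188	1503	567	2826	1415	1234	6014	2918
7	526	2590	1211	631	3007	1039	1157	5597	2250
8	301	1637	851	215	1434	754	516	3071	1605
9	357	1966	1011	371	2082	1007	728	4048	2018
10	207	1118	555	200	1182	598	407	2300	1153
11	128	762	449	121	855	496	249	1617	945
12	388	2133	869	361	1759	896	749	3892	1765
13	489	2425	1293	515	2467	1321	1004	4892	2614
14	508	2693	1226	523	2716	1175	1031	5409	2401
15	284	1852	893	288	1828	797	572	3680	1690
16	147	817	498	139	894	509	286	1711	1007
17	348	1630	585	215	905	474	563	2535	1059
18	192	964	479	176	1127	479	368	2091	958
X	220	1018	591	216	1165	618	436	2183	1209
Y	4	14	6	1	6	6	5	20	12
Unplaced scaffolds	1077	7726	2251	812	4387	2212	1889	12113	4463
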