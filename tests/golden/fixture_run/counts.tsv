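feature	control_1	control_2	control_3	d7_1	d7_2	d7_3	d14_1	d14_2	d14_3	d21_1	d21_2	d21_3	d28_1	d28_2	d28_3
gene_0001	25	17	21	8	6	1	1	3	2	2	8	2	6	6	2
gene_0002	63	72	70	27	27	28	8	7	8	24	14	16	45	24	17
gene_0003	523	679	1262	182	168	332	93	94	96	188	147	304	290	294	245
gene_0004	332	421	389	171	105	91	65	63	76	88	151	137	218	178	197
gene_0005	211	358	501	82	100	98	29	38	37	94	60	52	135	115	109
gene_0006	361	422	473	103	104	107	60	27	70	118	107	101	126	143	147
gene_0007	186	343	304	97	69	97	30	22	39	57	60	65	83	69	69
gene_0008	29	36	18	17	3	14	6	5	5	11	3	2	6	5	5
gene_0009	163	280	264	1867	2163	2044	1249	1493	2183	688	508	703	319	342	245
gene_0010	260	323	242	2915	1617	2963	1193	1343	1456	405	435	770	361	161	256
gene_0011	247	484	416	3814	3317	3061	3090	2870	1931	1144	953	731	461	390	472
gene_0012	261	304	221	2442	1589	3297	1923	1386	1386	611	403	702	375	210	235
gene_0013	124	178	149	1812	1684	2454	1163	1047	1295	403	372	378	154	266	175
gene_0014	285	267	435	2734	1834	2190	2019	1765	1080	757	565	670	378	270	174
gene_0015	131	291	241	2559	1722	1502	1028	769	1085	510	492	403	344	131	197
gene_0016	13	14	19	169	192	155	85	77	67	39	49	58	30	13	13
gene_0017	124	130	143	222	180	275	1269	962	938	606	769	706	1016	606	415
gene_0018	51	85	92	205	127	156	687	565	427	423	351	545	368	420	292
gene_0019	13	15	26	42	37	59	98	156	116	106	98	111	96	79	53
gene_0020	12	11	31	38	37	54	157	154	109	64	54	87	143	84	53
gene_0021	44	39	46	122	107	110	291	176	185	159	111	244	228	131	204
gene_0022	24	88	89	182	129	150	649	489	366	458	573	569	505	412	319
gene_0023	82	143	113	231	168	225	614	873	459	608	482	491	707	416	200
gene_0024	42	43	51	84	67	132	246	171	348	185	228	234	251	164	188
gene_0025	268	376	352	311	173	392	303	301	186	203	221	206	307	220	257
gene_0026	102	123	245	142	81	145	161	152	182	161	141	238	152	142	132
gene_0027	104	80	100	95	114	97	90	87	112	97	116	88	85	83	84
gene_0028	38	30	47	28	38	24	19	20	40	39	22	38	66	26	21
gene_0029	129	195	249	145	107	129	163	157	147	179	146	172	178	143	163
gene_0030	385	393	531	481	349	524	358	335	323	433	338	541	579	399	321
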