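sample_id	OTU001	OTU002	OTU003	OTU004	OTU005	OTU006	OTU007	OTU008	OTU009	OTU010	OTU011	OTU012	OTU013	OTU014	OTU015	OTU016	OTU017	OTU018	OTU019	OTU020	OTU021	OTU022	OTU023	OTU024	OTU025	OTU026	OTU027	OTU028	OTU029	OTU030	OTU031	OTU032	OTU033	OTU034	OTU035	OTU036	OTU037	OTU038	OTU039	OTU040
S01	431	29	75	563	186	318	1162	74	133	1911	31	316	189	4	529	1	4	417	205	223	11826	76	549	132	324	421	102	49	20	3693	18334	968	131	17	3	64	8918	132	17	118
S02	326	19	57	438	171	229	1000	60	81	1564	21	293	133	3	474	0	7	321	149	168	9228	58	450	100	262	332	86	36	22	2913	14620	857	119	15	1	48	7150	116	12	111
S03	373	24	62	477	169	276	990	61	79	1665	19	291	150	7	415	0	3	317	172	190	9646	72	456	122	316	364	104	41	13	3060	15180	892	125	18	5	47	7445	125	15	101
S04	74	5	11	105	41	52	193	15	21	317	6	57	29	1	94	0	1	59	45	33	2157	10	105	23	64	80	15	4	0	660	3315	182	34	7	1	11	1634	19	3	17
S05	475	27	61	561	215	329	1227	88	124	2051	20	372	155	1	567	1	11	397	203	212	11977	69	575	122	365	441	105	60	20	3820	18679	1075	140	24	2	62	9225	137	13	129
S06	167	10	24	174	87	111	400	25	41	688	13	114	58	2	188	0	3	142	71	80	4074	16	212	41	121	126	35	11	5	1287	6449	361	38	8	0	28	3202	48	2	61
S07	275	14	38	347	123	215	801	46	54	1291	18	181	109	2	328	1	4	260	126	123	7498	44	358	89	242	313	65	30	11	2345	11822	638	90	20	2	35	5643	94	11	88
S08	462	45	65	539	211	280000	1202	73	104	1937	28	334	158	10	561	1	8	379	201	207	11272	67	555	142	343	452	109	38	16	3503	18121	1019	136	29	2	68	8640	109	19	116
S09	217	8	29	264	103	160	567	33	46	996	9	188	87	3	260	0	6	202	106	102	5751	41	304	58	174	211	33	22	9	1811	9037	484	83	8	1	37	4362	67	8	45
S10	151	8	20	202	78	124	450	31	48	735	18	123	74	4	201	0	5	169	87	86	4458	23	212	43	133	181	37	13	6	1360	7005	372	44	4	3	20	3324	42	4	53
S11	147	10	25	158	77	115	405	26	43	686	12	133	72	1	177	0	6	143	71	81	3841	29	223	37	112	149	36	16	10	1242	6242	396	53	11	2	11	3021	44	5	40
S12	366	28	57	471	179	272	1015	67	88	1633	19	298	122	3	447	1	6	368	174	177	9882	73	425	107	273	356	84	43	8	3178	15387	808	126	16	0	50	7420	110	11	104
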