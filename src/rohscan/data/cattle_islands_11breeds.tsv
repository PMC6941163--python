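group	chrom	start_bp	end_bp	n_snps	length_kb
HO	1	82928948	85264656	46	2365
HO	9	24369582	25408468	20	1038
HO	10	36486868	36807581	6	320
HO	10	52190618	61064570	128	8873
HO	13	4755215	6822805	40	2067
HO	16	74532751	75892097	28	1359
HO	20	25850728	32074342	73	6223
HO	20	34728244	36917645	41	2189
HO	22	21266612	23914818	44	2648
RW	1	82951366	85525315	46	2573
RW	9	24369582	25359074	19	989
RW	14	25254540	25638580	6	384
RW	18	13901770	18449746	77	4547
RW	18	23196347	25471374	44	2275
RW	20	24544146	36311419	149	11767
RW	22	23365188	23914818	12	549
RW	26	21180893	23071595	35	1890
RW	29	40858913	44085769	57	3226
SM	1	103675933	105570832	31	1894
SM	1	155955828	156710174	14	754
SM	4	50547931	51370504	6	822
SM	5	63555403	64190317	9	634
SM	5	70338965	71546802	18	1207
SM	6	37252345	42714287	132	5461
SM	6	65217698	65978639	8	760
SM	6	67752994	73254801	78	5501
SM	6	81499583	82047313	7	547
SM	7	41565963	46354401	72	4788
SM	12	26967177	27337843	9	370
SM	14	57672324	58740723	16	1068
SM	16	42892437	45552538	29	2660
SM	16	46069918	47201903	18	1131
SM	20	48114351	50086666	35	1972
SM	28	2181928	2924302	5	742
LM	1	63421529	64276370	14	854
LM	1	80548510	81656974	12	1108
LM	1	133000000	135000000	26	1597
LM	2	35126	12632490	206	12597
LM	4	45577225	46381877	6	804
LM	7	58809602	58923345	4	113
LM	10	45864066	47664187	36	1800
LM	14	22643306	29543761	134	6900
HH	1	73757146	76938175	47	3181
HH	2	68877969	72583890	32	3705
HH	3	105000000	106000000	14	521
HH	5	75114559	79165498	62	4050
HH	6	65380200	74354100	131	8973
HH	7	107000000	108000000	27	1237
HH	11	28946979	29079159	4	132
HH	13	64253779	65817864	21	1564
HH	16	43371269	45376614	25	2005
HH	20	39538676	44414152	96	4875
CH	5	53263967	62180846	94	8916
CH	6	36708862	40063618	72	3354
CH	7	28182762	31973748	50	3790
CH	11	60738925	61700872	11	961
CH	14	18756025	29543761	191	10787
MO	1	32509969	33036107	11	526
MO	1	99477567	101000000	29	1385
MO	1	139000000	142000000	41	2840
MO	2	29055572	29627722	16	572
MO	6	36829725	40580921	82	3751
MO	6	70349791	73092782	55	2742
MO	7	41805531	44136041	37	2330
MO	8	49981054	50725941	18	744
MO	9	40287003	44951803	42	4664
MO	9	46351157	50728426	67	4377
MO	11	72069940	72864887	12	794
MO	16	22179895	23037476	7	857
MO	16	43424406	47558131	50	4133
MO	23	9020371	10665897	34	1645
BG	1	102000000	106000000	68	4203
BG	5	75794378	77311671	33	1517
BG	6	9404648	10424905	10	1020
BG	7	42521261	46626888	38	4105
BG	10	70894537	71985171	27	1090
BG	11	20558025	21817694	36	1259
BG	13	47546608	50701854	37	3155
BG	13	53618942	55006836	21	1387
BG	14	24145838	26473490	44	2327
BG	18	36146356	38147823	25	2001
BG	26	18335079	24531763	100	6196
BG	26	25170222	25657642	10	487
BG	28	16727989	17304235	14	576
RP	1	4648383	5351369	12	702
RP	1	31269020	31551425	3	282
RP	1	104000000	105000000	13	1042
RP	8	55145132	57339395	39	2194
RP	8	58789069	60589007	34	1799
RP	8	61536940	63000189	32	1463
RP	8	63162363	63901386	16	739
RP	11	55809281	60250739	49	4441
RP	13	53347036	57016938	68	3669
RP	14	23384687	26597692	57	3213
RP	16	42892437	46625869	37	3733
RP	17	34139617	37933239	42	3793
ZR	1	83838758	83916372	3	77
ZR	4	75890428	77635835	31	1745
ZR	5	76317361	77311671	26	994
ZR	10	11707725	12020216	6	312
ZR	10	70736766	72202330	33	1465
ZR	11	29822671	30945111	31	1122
ZR	13	46150079	47990990	40	1840
ZR	13	50950127	51165507	4	215
ZR	13	52837622	56190025	57	3352
ZR	14	24275232	28332133	45	4056
ZR	15	52311393	52910307	14	598
ZR	18	13901770	15594562	26	1692
ZR	18	23196347	23949849	21	753
ZR	26	19727292	23461479	63	3734
ZB	1	82787221	84515050	19	1727
ZB	2	784712	2415461	36	1630
ZB	2	78556325	80096393	30	1540
ZB	5	75627333	77679706	43	2052
ZB	7	44901489	47213804	22	2312
ZB	7	66303743	66645827	7	342
ZB	8	87308122	88974063	26	1665
ZB	10	52606823	54514075	44	1907
ZB	10	56464919	56812824	3	347
ZB	11	44061322	45008048	20	946
ZB	12	65092442	65481742	6	389
ZB	13	48485992	50813233	32	2327
ZB	14	23054179	26542736	61	3488
ZB	16	43810410	45017787	14	1207
ZB	18	14115136	15099438	14	984
ZB	26	20365711	23129849	45	2764
ZB	27	17593646	18991970	27	1398
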