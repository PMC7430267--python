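sample_id	population	specimen_id	taxon	clade	locality	latitude	longitude	introduced_candidate
1	1	DBW5974	B. major	4	Los Angeles Co., CA, USA	34.2233	-118.4300	False
2	2	MVZ249023	B. major	4	Los Angeles Co., CA, USA	34.0492	-118.3297	False
3	3	MVZ154320	B. major	4	Los Angeles Co., CA, USA	34.0184	-118.3155	False
4	4	MVZ244159	B. major	4	Los Angeles Co., CA, USA	33.9885	-118.3886	False
5	5	MVZ236063	B. major	4	Los Angeles Co., CA, USA	33.8666	-118.2555	False
6	6	MVZ206271	B. major	4	Orange Co., CA, USA	33.8729	-117.7417	False
7a	7	MVZ225581	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7b	7	MVZ225582	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7c	7	MVZ225584	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7d	7	MVZ225585	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7e	7	MVZ225586	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7f	7	MVZ225587	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7g	7	MVZ225588	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7h	7	MVZ225589	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7i	7	MVZ225590	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
7j	7	MVZ225591	B. major	4	Orange Co., CA, USA	33.6619	-117.9410	False
8	8	StarrRanch	B. major	4	Orange Co., CA, USA	33.6303	-117.5539	False
9	9	MVZ266823	B. major	4	Orange Co., CA, USA	33.5134	-117.5790	False
10	10	MVZ222784	B. major	4	Orange Co., CA, USA	33.4625	-117.7083	False
11	11	MVZ222813	B. major	4	San Diego Co., CA, USA	33.4517	-117.5586	False
12	12	MVZ168561	B. major	4	Los Angeles Co., CA, USA	33.3675	-118.4701	False
13	13	MVZ154341	B. major	4	Los Angeles Co., CA, USA	33.3399	-118.3294	False
14	14	CJE162	B. major	4	Los Angeles Co., CA, USA	33.4670	-118.5395	False
15	15	MVZ236057	B. major	1	San Bernardino Co., CA, USA	34.2360	-117.4119	False
16a	16	MVZ236068	B. major	1	San Bernardino Co., CA, USA	34.1867	-117.1800	False
16b	16	MVZ236069	B. major	1	San Bernardino Co., CA, USA	34.1867	-117.1800	False
17	17	MVZ167815	B. major	1	Riverside Co., CA, USA	33.8565	-117.6141	False
18	18	MVZ222788	B. major	3	San Bernardino Co., CA, USA	34.0093	-117.1788	False
19	19	Perris	B. major	3	Riverside Co., CA, USA	33.8686	-117.1902	False
20	20	Motte	B. major	3	Riverside Co., CA, USA	33.8023	-117.2506	False
21	21	Skinner	B. major	3	Riverside Co., CA, USA	33.5899	-117.0233	False
22	22	MVZ167880	B. major	2	Riverside Co., CA, USA	33.8941	-116.7932	False
23	23	MVZ228296	B. major	2	Riverside Co., CA, USA	33.8889	-116.6869	False
24	24	MVZ215862	B. major	5	Orange Co., CA, USA	33.5983	-117.4612	False
25	25	MVZ222912	B. major	5	San Diego Co., CA, USA	33.4524	-117.5499	False
26	26	MVZ225614	B. major	5	San Diego Co., CA, USA	33.4200	-117.5300	False
27	27	MVZ225610	B. major	5	San Diego Co., CA, USA	33.4600	-117.5100	False
28a	28	MVZ225607	B. major	5	San Diego Co., CA, USA	33.4705	-117.4722	False
28b	28	MVZ225608	B. major	5	San Diego Co., CA, USA	33.4705	-117.4722	False
29	29	MVZ222877	B. major	5	San Diego Co., CA, USA	33.4578	-117.4053	False
30	30	MVZ222787	B. major	5	Riverside Co., CA, USA	33.5141	-117.3868	False
31	31	MVZ236121	B. major	5	Riverside Co., CA, USA	33.5037	-117.3365	False
32	32	MVZ225605	B. major	5	San Diego Co., CA, USA	33.3638	-117.4951	False
33	33	MVZ225623	B. major	5	San Diego Co., CA, USA	33.3700	-117.4300	False
34	34	MVZ222925	B. major	5	San Diego Co., CA, USA	33.4100	-117.2900	False
35	35	MVZ222794	B. major	5	San Diego Co., CA, USA	33.3167	-117.4697	False
36	36	MVZ225644	B. major	5	San Diego Co., CA, USA	33.3400	-117.3700	False
37	37	MVZ222914	B. major	5	San Diego Co., CA, USA	33.3100	-117.2800	False
38	38	MVZ225705	B. major	5	San Diego Co., CA, USA	33.3000	-116.9100	False
39	39	MVZ155748	B. major	6	San Diego Co., CA, USA	33.3011	-116.8849	False
40a	40	MVZ226688	B. major	6	San Diego Co., CA, USA	33.2754	-116.8527	False
40b	40	MVZ226689	B. major	6	San Diego Co., CA, USA	33.2754	-116.8527	False
40c	40	MVZ226690	B. major	6	San Diego Co., CA, USA	33.2754	-116.8527	False
41	41	MVZ181987	B. major	6	San Diego Co., CA, USA	33.2999	-116.7994	False
42	42	MVZ236072	B. major	6	San Diego Co., CA, USA	33.2528	-116.7717	False
43	43	MVZ225682	B. major	6	San Diego Co., CA, USA	33.1670	-116.7387	False
44	44	MVZ155765	B. major	6	San Diego Co., CA, USA	33.1592	-117.0311	False
45	45	WAP	B. major	6	San Diego Co., CA, USA	33.0976	-116.9795	False
46	46	MVZ272606	B. major	6	San Diego Co., CA, USA	33.0848	-116.9164	False
47a	47	MVZ181447	B. major	6	San Diego Co., CA, USA	33.0082	-116.9569	False
47b	47	MVZ181448	B. major	7	San Diego Co., CA, USA	33.0082	-116.9569	False
48a	48	MVZ225703	B. major	6	San Diego Co., CA, USA	33.0705	-116.8060	False
48b	48	MVZ225704	B. major	7	San Diego Co., CA, USA	33.0705	-116.8060	False
49	49	APG51	B. major	6	San Diego Co., CA, USA	33.0217	-117.2805	False
50	50	Torrey2	B. major	6	San Diego Co., CA, USA	32.9414	-117.2505	False
51	51	Torrey3	B. major	8	San Diego Co., CA, USA	32.9250	-117.2574	False
52	52	MVZ236077	B. major	8	San Diego Co., CA, USA	32.8275	-117.2612	False
53	53	Pointsettia	B. major	8	San Diego Co., CA, USA	32.7452	-117.2252	False
54a	54	GP411	B. major	8	Baja California, Mexico	32.4139	-117.2442	False
54b	54	GP414	B. major	8	Baja California, Mexico	32.4139	-117.2442	False
55	55	Torrey1	B. major	7	San Diego Co., CA, USA	32.9149	-117.2500	False
56	56	DBW4920	B. major	7	San Diego Co., CA, USA	32.8918	-117.0971	False
57a	57	MVZ225986	B. major	7	San Diego Co., CA, USA	33.0219	-116.8022	False
57b	57	MVZ225987	B. major	7	San Diego Co., CA, USA	33.0219	-116.8022	False
57c	57	MVZ225988	B. major	7	San Diego Co., CA, USA	33.0219	-116.8022	False
58	58	MVZ225689	B. major	7	San Diego Co., CA, USA	33.0202	-116.8047	False
c1	c1	ELJ2052	B. incognitus	CC	Monterey Co., CA, USA	35.9138	-121.3639	False
c2	c2	MVZ266756	B. incognitus	CC	Monterey Co., CA, USA	35.8879	-121.4405	False
c3	c3	MVZ266750	B. incognitus	CC	Monterey Co., CA, USA	35.8219	-121.3478	False
c4	c4	MVZ224790	B. incognitus	CC	San Luis Obispo Co., CA, USA	35.6931	-121.0909	False
c5	c5	MVZ237245	B. minor	CC	San Luis Obispo Co., CA, USA	35.5419	-120.8180	False
c6	c6	ELJ1775	B. sp.	CC	Santa Barbara Co., CA, USA	34.5783	-120.6436	False
i1	i1	MVZ221043	B. major	4	Kings Co., CA, USA	36.3308	-119.6500	True
i2a	i2	ELJ2149	B. major	4	Kern Co., CA, USA	35.3655	-118.9129	True
i2b	i2	ELJ2150	B. major	4	Kern Co., CA, USA	35.3655	-118.9129	True
s1	s1	MVZ222553	B. m. aridus	S	Riverside Co., CA, USA	33.6225	-116.4018	False
s2	s2	MVZ225684	B. major	S	San Diego Co., CA, USA	32.9997	-116.7998	False
s3	s3	Marron	B. major	S	San Diego Co., CA, USA	32.6272	-116.7770	False
s4a	s4	Mision1	B. major	S	Baja California, Mexico	32.0930	-116.8571	False
s4b	s4	Mision3	B. major	S	Baja California, Mexico	32.0930	-116.8571	False
s5	s5	APG72	B. major	S	Baja California, Mexico	32.2046	-116.5044	False
s6	s6	IBH14152	B. major	S	Baja California, Mexico	31.9536	-116.7350	False
s7	s7	APG36	B. major	S	Baja California, Mexico	31.5672	-116.4720	False
s8	s8	DBW6026	B. major	S	Baja California, Mexico	30.9582	-115.5020	False
s9	s9	APG50	B. major	S	Baja California, Mexico	30.4900	-116.0158	False
s10	s10	MVZ232916	B. pacificus	S	Santa Barbara Co., CA, USA	34.0121	-120.0562	False
s11	s11	MVZ156098	B. pacificus	S	Santa Barbara Co., CA, USA	34.0178	-119.8183	False
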