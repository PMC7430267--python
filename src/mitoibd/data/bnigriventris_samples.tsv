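sample_id	population	specimen_id	taxon	clade	locality	latitude	longitude	introduced_candidate
1	1	MVZ267018	B. nigriventris	m-E	Ventura Co., CA, USA	34.4291	-119.0908	False
2a	2	MVZ267019	B. nigriventris	m-E	Ventura Co., CA, USA	34.4395	-119.0808	False
2b	2	MVZ267020	B. nigriventris	m-E	Ventura Co., CA, USA	34.4395	-119.0808	False
2c	2	MVZ267022	B. nigriventris	m-E	Ventura Co., CA, USA	34.4395	-119.0808	False
3	3	MVZ267026	B. nigriventris	m-E	Ventura Co., CA, USA	34.4427	-119.0769	False
4	4	MVZ266987	B. nigriventris	m-E	Ventura Co., CA, USA	34.3650	-119.0622	False
5a	5	MVZ267029	B. nigriventris	m-E	Ventura Co., CA, USA	34.2790	-119.1406	False
5b	5	MVZ267030	B. nigriventris	m-E	Ventura Co., CA, USA	34.2790	-119.1406	False
6	6	MVZ236114	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.5742	-118.6908	False
7	7	MVZ220496	B. nigriventris	m-c	Ventura Co., CA, USA	34.4869	-118.9001	False
8	8	MVZ236118	B. nigriventris	m-c	Ventura Co., CA, USA	34.3803	-118.8942	False
9	9	MVZ236149	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.3789	-118.5244	False
10	10	MVZ266995	B. nigriventris	m-c	Ventura Co., CA, USA	34.0843	-119.0356	False
11	11	MVZ266981	B. nigriventris	m-c	Ventura Co., CA, USA	34.1537	-118.9500	False
12	12	MVZ267004	B. nigriventris	m-c	Ventura Co., CA, USA	34.1842	-118.9107	False
13	13	MVZ244086	B. nigriventris	m-c	Ventura Co., CA, USA	34.1267	-118.8557	False
14	14	MVZ266964	B. nigriventris	m-c	Ventura Co., CA, USA	34.2107	-118.8051	False
15	15	MVZ266829	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.1444	-118.7662	False
16	16	MVZ236122	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.0820	-118.7051	False
17	17	MVZ225995	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.0900	-118.6200	False
18	18	DBW5422	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.1214	-118.3981	False
19a	19	MVZ225707	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.0105	-118.3683	False
19b	19	MVZ225708	B. nigriventris	m-c	Los Angeles Co., CA, USA	34.0105	-118.3683	False
20	20	MVZ226699	B. nigriventris	m-W	Los Angeles Co., CA, USA	34.5836	-118.3526	False
21a	21	MVZ222695	B. nigriventris	m-W	Los Angeles Co., CA, USA	34.2923	-117.8390	False
21b	21	MVZ191665	B. nigriventris	m-W	Los Angeles Co., CA, USA	34.2915	-117.8384	False
22	22	MVZ206251	B. nigriventris	m-W	Los Angeles Co., CA, USA	34.3029	-117.8366	False
23	23	MVZ222706	B. nigriventris	m-W	Los Angeles Co., CA, USA	34.2382	-117.8618	False
24	24	MVZ225706	B. nigriventris	m-W	Los Angeles Co., CA, USA	34.0578	-117.8223	False
25	25	MVZ236159	B. nigriventris	m-W	Orange Co., CA, USA	33.5692	-117.7473	False
26	26	MVZ222715	B. nigriventris	m-W	Orange Co., CA, USA	33.5116	-117.7509	False
27	27	MVZ215861	B. nigriventris	m-W	Orange Co., CA, USA	33.6066	-117.5094	False
28	28	MVZ222716	B. nigriventris	m-W	Riverside Co., CA, USA	33.5180	-117.3914	False
29	29	MVZ272607	B. nigriventris	island	Santa Barbara Co., CA, USA	33.9966	-119.7276	False
30	30	MVZ222760	B. nigriventris	island	Santa Barbara Co., CA, USA	33.9962	-119.7213	False
n1	n1	MVZ225996	B. nigriventris	N	Monterey Co., CA, USA	35.8371	-121.3902	False
n2	n2	MVZ237247	B. nigriventris	N	San Luis Obispo Co., CA, USA	35.5419	-120.8180	False
n3	n3	MVZ237261	B. nigriventris	N	San Luis Obispo Co., CA, USA	35.4760	-120.8452	False
n4	n4	ELJ2209	B. nigriventris	N	San Luis Obispo Co., CA, USA	35.3937	-120.4657	False
n5	n5	SSS32305	B. nigriventris	N	San Luis Obispo Co., CA, USA	35.2617	-119.9403	False
n6	n6	MVZ266895	B. nigriventris	N	San Luis Obispo Co., CA, USA	35.1945	-120.4538	False
n7	n7	SSS32316	B. nigriventris	N	San Luis Obispo Co., CA, USA	35.1755	-120.7813	False
n8	n8	SSS32306	B. nigriventris	N	San Luis Obispo Co., CA, USA	35.0778	-119.7737	False
n9	n9	MVZ272646	B. nigriventris	N	Kern Co., CA, USA	34.9841	-119.1862	False
n10	n10	MVZ154037	B. nigriventris	N	Santa Barbara Co., CA, USA	34.7947	-120.0454	False
n11	n11	MVZ266960	B. nigriventris	N	Santa Barbara Co., CA, USA	34.5839	-120.5603	False
n12	n12	MVZ266950	B. nigriventris	N	Santa Barbara Co., CA, USA	34.5334	-120.0749	False
n13a	n13	MVZ266996	B. nigriventris	N	Ventura Co., CA, USA	34.4693	-119.2239	False
n13b	n13	MVZ266997	B. nigriventris	N	Ventura Co., CA, USA	34.4693	-119.2239	False
n15	n15	MVZ266946	B. nigriventris	N	Santa Barbara Co., CA, USA	34.4426	-119.6435	False
n16	n16	MVZ266986	B. nigriventris	N	Ventura Co., CA, USA	34.4384	-119.1245	False
n17	n17	MVZ266949	B. nigriventris	N	Santa Barbara Co., CA, USA	34.3878	-119.4981	False
n18	n18	MVZ267040	B. nigriventris	N	Ventura Co., CA, USA	34.3512	-119.1474	False
n19	n19	MVZ267009	B. nigriventris	N	Ventura Co., CA, USA	34.3297	-119.1411	False
n20	n20	MVZ266962	B. nigriventris	N	Ventura Co., CA, USA	34.2924	-119.2270	False
n21	n21	MVZ267031	B. nigriventris	N	Ventura Co., CA, USA	34.2790	-119.1406	False
MVZ226708	MVZ226708	MVZ226708	B. bramei	Sierran	Tulare Co., CA, USA	35.8342	-118.4411	False
MVZ226712	MVZ226712	MVZ226712	B. bramei	Sierran	Kern Co., CA, USA	35.7763	-118.4268	False
CAS219746	CAS219746	CAS219746	B. relictus	Sierran	Kern Co., CA, USA	35.4786	-118.9589	False
MVZ267162	MVZ267162	MVZ267162	B. relictus	Sierran	Kern Co., CA, USA	35.4669	-118.5667	False
MVZ220498	MVZ220498	MVZ220498	B. simatus	Sierran	Kern Co., CA, USA	35.5747	-118.5280	False
ELJ1922	ELJ1922	ELJ1922	B. simatus	Sierran	Kern Co., CA, USA	35.5669	-118.4013	False
MVZ232842	MVZ232842	MVZ232842	B. simatus	Sierran	Kern Co., CA, USA	35.5600	-118.4431	False
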