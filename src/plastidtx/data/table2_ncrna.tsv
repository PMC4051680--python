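id	subtype	partners	start	end	strand	log_abundance	partner_log_abundance	printed_log_ratio
nc1	B3B	psbA	200	1495	P	8.75	12.95	-4.2
nc2	B3A	matK	2165	2310	P	1.7	3.85	-2.15
nc3	B5	trnK-UUU	3257	3927	P	3.85	5.31	-1.46
nc4	B1	trnK-UUU	4062	4338	P	4.18	4.44	-0.26
nc5	B3B	trnQ-UUG	6617	7053	P	7.64	1.7	5.93
nc6	B4	psbK;psbI	7413	7869	N	5.02	9.37	-4.35
nc7	B1	trnS-GCU	8278	8541	P	4.18	1.7	2.47
nc8	B3A	atpA	10264	10519	P	2.85	6.38	-3.52
nc9	B3A	atpA	10960	11171	P	2.85	8.65	-5.79
nc10	B2	atpH	13082	13272	P	1.85	8.44	-6.58
nc11	B1	atpH	13288	13456	P	1.7	8.45	-6.75
nc12	A2	atpH;atpI	13547	13720	P	1.7	4.66	-2.96
nc13	B2	rpoC2	16319	16513	P	1.85	1.85	0
nc14	B3A	rpoC2	16624	16832	P	2.85	4.18	-1.32
nc15	B3A	rpoC2	17149	17355	P	1.85	1.85	0
nc16	B3A	rpoC2	18119	18313	P	1.85	1.7	0.15
nc17	B3A	rpoC2	19678	19892	P	1.85	2.85	-1
nc18	B3A	rpoC1	21473	21691	P	1.85	3.85	-2
nc19	B3B	petN	27966	28380	N	3.44	5.18	-1.74
nc20	A3	petN;psbM	28478	28711	N	4.44	6.85	-2.42
nc21	A3	petN;psbM	28793	28948	N	2.85	5.44	-2.58
nc22	B4	trnD-GUC;trnE-UUC	29689	30029	P	4.18	4.18	0
nc23	A2	trnT-GGU;psbD	31586	31743	N	1.7	7.66	-5.96
nc24	B3A	psbD	32467	32646	N	1.85	12.95	-11.09
nc25	B3A	psbD	32730	32891	N	1.7	11.1	-9.39
nc26	B3A	psbC	33317	33469	N	1.7	11.64	-9.94
nc27	B3A	psbC	33534	33703	N	1.7	9.7	-8
nc28	B3A	psbC	34011	34229	N	3.44	11.47	-8.03
nc29	B3B	trnG-GCC	35562	35803	N	3.44	1.7	1.74
nc30	B4	rps14;psaB	36400	36644	P	3.44	10.13	-6.69
nc31	B3A	psaB	36801	36967	P	1.7	9.52	-7.82
nc32	B3A	psaB	37108	37418	P	1.85	8.3	-6.44
nc33	B3A	psaB	37587	37873	P	1.85	10.96	-9.1
nc34	A2	psaA;ycf3	41278	41422	P	1.7	6.61	-4.91
nc35	B2	ycf3	41854	42231	P	5.85	7.35	-1.49
nc36	B5	ycf3	42290	42563	P	5.02	8.16	-3.13
nc37	B1	ycf3	43721	43913	P	1.85	7.47	-5.61
nc38	A4	ycf3;trnS-GGA	43994	44309	N	5.02	3.58	1.44
nc39	A4	ycf3;trnS-GGA	44037	44246	P	4.18	4.52	-0.34
nc40	A3	ycf3;trnS-GGA	44256	44483	P	1.85	2.94	-1.09
nc41	B3A	rps4	45313	45558	P	1.85	5.76	-3.91
nc42	A3	trnT-UGU;trnL-UAA	46416	46572	N	1.85	1.7	0.15
nc46	B2	ndhJ	47866	48115	P	1.85	5.15	-3.3
nc47	B3A	ndhJ	48199	48592	P	4.18	6.81	-2.63
nc48	B3A	ndhK	49174	49332	P	1.85	8.54	-6.69
nc49	B4	ndhK;ndhC	49508	49643	P	1.7	7.83	-6.13
nc50	A2	ndhC;trnV-UAC	50054	50277	P	4.18	1.7	2.47
nc51	A1	ndhC;trnV-UAC	50468	50658	N	2.85	1.7	1.15
nc52	B3A	atpE	51910	52127	P	3.85	4.85	-1
nc53	B4	atpE;atpB	52214	52383	P	1.7	4.18	-2.47
nc54	B3A	atpB	52500	52913	P	3.85	7.18	-3.32
nc55	B3A	atpB	53004	53161	P	1.7	6.02	-4.32
nc56	B3A	atpB	53225	53392	P	2.85	7.66	-4.81
nc57	B3A	atpB	53411	53739	P	1.85	8.14	-6.29
nc58	A3	atpB;rbcL	53936	54123	N	1.85	1.78	0.08
nc59	A3	atpB;rbcL	54170	54342	P	1.85	1.78	0.08
nc60	B3A	rbcL	55162	55356	N	1.85	10.45	-8.6
nc61	B2	rbcL	55814	56018	N	4.18	9.49	-5.31
nc62	A4	rbcL;accD	56088	56453	P	3.85	1.78	2.07
nc63	A4	rbcL;accD	56123	56306	N	1.7	1.78	-0.08
nc64	B3A	accD	56690	56859	N	1.7	5.85	-4.15
nc65	B3A	accD	57105	57313	N	1.85	6.56	-4.7
nc66	B3A	accD	57809	57994	N	1.7	4.44	-2.74
nc67	B3A	petA	61536	61883	N	3.85	5.56	-1.7
nc68	A3	petA;psbJ	62307	62606	N	3.44	5.44	-2
nc69	B3B	psbJ	63114	63384	P	3.85	5.56	-1.7
nc70	B4	psbL;psbE	63555	64076	P	4.18	10.41	-6.24
nc71	A3	psbE;petL	64296	64452	P	1.7	1.7	0
nc72	B1	petL	64638	64907	N	1.7	1.85	-0.15
nc73	B2	rpl33	66678	66888	N	2.85	1.7	1.15
nc74	B3A	rps18	66932	67168	N	2.85	1.85	1
nc75	B5	clpP	70399	70562	P	1.7	1.7	0
nc76	B3A	clpP	70570	70769	P	2.85	4.66	-1.81
nc77	B3A	psbB	71265	71434	N	1.7	11.37	-9.66
nc78	B3A	psbB	71439	71905	N	5.02	12.58	-7.55
nc79	B3A	psbB	71946	72174	N	1.85	12.1	-10.25
nc80	B2	psbB	72517	72749	N	4.44	10.26	-5.82
nc81	B3A	psbH	73361	73511	N	2.85	3.85	-1
nc82	B5	petB	73656	73853	N	5.31	6.5	-1.18
nc83	B5	petD	75249	75406	N	1.7	6.31	-4.61
nc84	B3A	rpoA	77012	77235	P	1.85	2.85	-1
nc85	B3A	rpoA	77295	77501	P	2.85	4.18	-1.32
nc86	B4	rps11;rpl36	78077	78255	P	1.7	4.44	-2.74
nc87	B2	rps8	78685	78840	P	1.7	4.18	-2.47
nc88	B5	rpl16	80787	80947	P	1.7	1.7	0
nc89	B3A	rpl2	82845	83279	P	4.66	1.7	2.96
nc90	B3A	rpl2	83907	84419	P	5.02	1.7	3.32
nc91	B3A	trnI-CAU	84630	84965	P	1.85	1.7	0.15
nc92	B4	ycf15;ndhB	92095	93270	P	6.18	1.7	4.47
nc93	B3A	ndhB	93447	93677	P	3.44	1.7	1.74
nc94	B5	ndhB	93763	93927	P	1.7	1.7	0
nc95	B3A	ndhB	94061	94678	P	5.02	1.7	3.32
nc96	B3A	rps7	95621	95904	P	2.85	1.7	1.15
nc97	B5	rps12	96267	96415	P	1.7	1.7	0
nc98	B1	rps12	96577	97076	P	4.44	1.7	2.74
nc99	B3A	ndhF	110141	110353	P	2.85	1.85	1
nc100	B1	rpl32	110951	111234	N	1.85	1.7	0.15
nc101	B3B	trnL-UAG	111376	111832	N	5.31	1.7	3.61
nc102	B3A	ccsA	112632	112844	N	1.85	1.85	0
nc103	B3A	ndhD	113867	114011	P	1.7	6.56	-4.85
nc104	B3A	ndhI	116816	116987	P	1.85	5.18	-3.32
nc105	B5	ndhA	118049	118354	P	3.85	3.44	0.42
nc106	B5	ndhA	118405	118556	P	1.7	3.44	-1.74
nc107	B3A	ndhA	118767	118932	P	1.7	6.66	-4.96
nc108	B3A	ndhA	119109	119245	P	1.7	5.56	-3.85
nc109	B3A	ycf1	122874	123076	P	1.85	1.7	0.15
nc110	B3A	ycf1	125963	126185	P	4.66	1.7	2.96
nc111	B3A	ycf1	126388	126722	P	4.18	1.7	2.47
nc112	A3	ycf1;trnN-GUU	126855	127066	P	2.85	1.7	1.15
nc113	B1	trnR-ACG	127767	127984	P	1.85	1.7	0.15
nc114	B3A	rrn5S	128072	128238	P	1.7	1.7	0
nc115	B4	rrn4.5S;rrn23S	128415	128902	P	5.02	1.7	3.32
nc116	B3A	rrn23S	129227	129443	P	1.85	1.7	0.15
nc117	B3A	rrn23S	130921	131307	P	3.85	1.7	2.15
nc118	B4	rrn23S;trnA-UGC	131390	131676	P	1.85	1.7	0.15
nc119	B4	trnA-UGC;trnI-GAU	132316	132606	P	5.44	1.7	3.74
nc120	B5	trnI-GAU	132771	132974	P	2.85	1.7	1.15
nc121	B1	trnI-GAU	133315	133511	P	1.85	1.7	0.15
nc122	B2	rrn16S	133763	133931	P	1.85	1.7	0.15
nc123	B3A	rrn16S	133980	134188	P	1.85	1.7	0.15
nc124	B3A	rrn16S	134232	134406	P	2.85	1.7	1.15
nc125	B3A	rrn16S	134640	134905	P	2.85	1.7	1.15
nc126	B3A	ycf15	142008	142191	P	1.7	1.7	0
nc127	B3A	ycf2	143031	143248	P	2.85	1.7	1.15
nc128	B3A	ycf2	143344	143498	P	1.7	1.7	0
nc129	B3A	ycf2	143716	143911	P	1.85	1.7	0.15
nc130	B3A	ycf2	144612	144875	P	3.85	1.7	2.15
nc131	B3A	ycf2	144928	145108	P	1.7	1.7	0
nc132	B3A	ycf2	145219	145440	P	1.85	1.7	0.15
nc133	B3A	ycf2	145870	146044	P	1.7	1.7	0
nc134	B3A	ycf2	146113	146463	P	3.44	1.7	1.74
nc135	B3A	ycf2	146671	146882	P	1.85	1.7	0.15
nc136	B3A	ycf2	147068	147240	P	1.7	1.7	0
nc137	B3A	ycf2	147266	147609	P	4.18	1.7	2.47
nc138	B3A	ycf2	148116	148261	P	1.7	1.7	0
nc139	B3A	ycf2	148435	148594	P	1.85	1.7	0.15
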