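id	name	start	end	strand	log_abundance	polycistron
psbA	psbA	392	1450	N	12.93	1
trnK-UUU	trnK-UUU	1672	4266	N	6.90	1
matK	matK	1972	3534	N	5.76	1
rps16	rps16	4834	5944	N	5.85
psbK	psbK	7380	7559	P	8.21	2
psbI	psbI	7905	8066	P	5.18	2
trnG-UCC	trnG-UCC	8923	9677	P	3.85
atpA	atpA	10042	11565	N	9.67	3
atpF	atpF	11661	12913	N	7.96	3
atpH	atpH	13187	13432	N	8.74	3
atpI	atpI	14403	15146	N	5.66	3
rps2	rps2	15374	16084	N	7.02	4
rpoC2	rpoC2	16293	20480	N	6.98	4
rpoC1	rpoC1	20638	23451	N	7.69	4
rpoB	rpoB	23478	26690	N	7.06	4
trnC-GCA	trnC-GCA	27834	27904	P	1.70	5
petN	petN	28061	28156	P	2.85	5
psbM	psbM	29133	29237	N	4.85
trnD-GUC	trnD-GUC	29758	29831	N	1.85	6
trnY-GUA	trnY-GUA	29942	30025	N	1.85	6
trnE-UUC	trnE-UUC	30097	30169	N	1.70	6
psbD	psbD	32159	33220	P	14.92	7
psbC	psbC	33168	34589	P	13.64	7
psbZ	psbZ	35262	35450	P	8.62	7
rps14	rps14	36188	36490	N	10.09	8
psaB	psaB	36613	38817	N	12.50	8
psaA	psaA	38843	41095	N	12.58	8
ycf3	ycf3	41886	43817	N	9.64
trnS-GGA	trnS-GGA	44634	44720	P	3.44
rps4	rps4	44997	45602	N	6.66
trnL-UAA	trnL-UAA	46728	47267	P	5.02	9
trnF-GAA	trnF-GAA	47566	47638	P	2.85	9
ndhJ	ndhJ	48171	48647	N	6.94	9
ndhK	ndhK	48758	49435	N	9.43	9
ndhC	ndhC	49487	49849	N	8.90	9
trnV-UAC	trnV-UAC	50799	51447	N	5.66
atpE	atpE	51904	52305	N	5.66	10
atpB	atpB	52302	53798	N	9.76	10
rbcL	rbcL	54563	56017	P	13.52
accD	accD	56708	58195	P	8.57
psaI	psaI	58658	58768	P	1.85
ycf4	ycf4	59224	59778	P	5.31
cemA	cemA	60326	61015	P	5.44
petA	petA	61221	62183	P	6.66
psbJ	psbJ	63245	63367	N	4.44	11
psbL	psbL	63497	63613	N	6.56	11
psbF	psbF	63637	63756	N	7.56	11
psbE	psbE	63771	64022	N	9.60	11
petL	petL	64829	64924	P	1.70	12
petG	petG	65103	65216	P	1.85	12
psaJ	psaJ	65939	66073	P	5.66
rps18	rps18	66890	67195	P	2.85
rpl20	rpl20	67427	67813	N	4.18
5'-rps12	5'-rps12	68623	68736	N	1.85
clpP	clpP	68860	70769	N	6.71
psbB	psbB	71218	72744	P	14.08
psbT	psbT	72921	73028	P	1.85	13
psbN	psbN	73089	73220	N	5.76
psbH	psbH	73308	73547	P	5.56	13
petB	petB	73673	75022	P	8.88	13
petD	petD	75216	76418	P	7.88	13
rpoA	rpoA	76595	77602	N	5.76	14
rps11	rps11	77674	78090	N	6.44	14
rpl36	rpl36	78200	78313	N	3.85	14
infA	infA	78409	78642	N	5.18	14
rps8	rps8	78769	79173	N	5.94	14
rpl14	rpl14	79363	79731	N	5.31	14
rpl16	rpl16	79863	81143	N	7.06	14
rps3	rps3	81279	81941	N	6.66	14
rpl22	rpl22	81926	82393	N	6.31	14
rps19	rps19	82463	82741	N	3.85	14
rpl2	rpl2	82801	84283	N	9.38	15
rpl2/2	rpl2	149748	151230	P
rpl23	rpl23	84302	84583	N	7.06	15
rpl23/2	rpl23	149448	149729	P
ycf2	ycf2	84911	91762	P	7.38
ycf2/2	ycf2	142269	149120	N
trnL-CAA	trnL-CAA	92362	92442	N	1.70	16
trnL-CAA/2	trnL-CAA	141589	141669	P
ndhB	ndhB	93002	95155	N	12.80	16
ndhB/2	ndhB	138876	141029	P
rps7	rps7	95484	95951	N	12.59	16
rps7/2	rps7	138080	138547	P
3'-rps12	3'-rps12	96005	96785	N	10.72	16
3'-rps12/2	3'-rps12	137246	138026	P
rrn16S	rrn16S	98690	100180	P	18.34	17
rrn16S/2	rrn16S	133851	135341	N
trnI-GAU	trnI-GAU	100479	101490	P	13.16	17
trnI-GAU/2	trnI-GAU	132541	133552	N
trnA-UGC	trnA-UGC	101555	102422	P	13.82	17
trnA-UGC/2	trnA-UGC	131609	132476	N
rrn23S	rrn23S	102581	105397	P	18.79	17
rrn23S/2	rrn23S	128634	131450	N
rrn4.5S	rrn4.5S	105497	105599	P	7.56	17
rrn4.5S/2	rrn4.5S	128432	128534	N
rrn5S	rrn5S	105824	105954	P	2.85	17
rrn5S/2	rrn5S	128077	128207	N
trnR-ACG	trnR-ACG	106188	106261	P	3.85	17
trnR-ACG/2	trnR-ACG	127770	127843	N
ndhF	ndhF	108206	110422	N	7.85
rpl32	rpl32	110875	111045	P	1.85
ccsA	ccsA	111907	112884	P	2.85
ndhD	ndhD	113116	114630	N	9.29	18
psaC	psaC	114766	115011	N	5.31	18
ndhE	ndhE	115262	115567	N	6.76	18
ndhG	ndhG	115783	116313	N	7.88	18
ndhI	ndhI	116689	117195	N	7.35	19
ndhA	ndhA	117276	119352	N	9.72	19
ndhH	ndhH	119354	120535	N	7.31	19
ycf1	ycf1	121333	126849	N	4.66
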