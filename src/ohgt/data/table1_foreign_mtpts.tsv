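row_id	recipient_species	recipient_lineage	accession	start	end	length	genes	bs	donor_lineage	donor_sister_flag	flank5_code	flank3_code	host_parasite_flag	source_ref
1	Amborella trichopoda	basal Magnoliophyta; Amborellales	KF754801	124144	127171	3028	psbC; psbD	-	Santalales	0	no1	no3	1	rice2013
2	Amborella trichopoda	basal Magnoliophyta; Amborellales	KF754803	3077656	3078925	1270	rbcL	-	Santalales	0	yes5	no3	1	rice2013
3	Amborella trichopoda	basal Magnoliophyta; Amborellales	KF754803	474251	476207	1957	psaA	-	rosids; fabids; Oxalidales	0	no3	no5	0	rice2013
4	Amborella trichopoda	basal Magnoliophyta; Amborellales	KF754799	57856	61814	3959	rps7; rps12; trnV; rrnS	-	rosids; fabids; Fagales; Fagaceae	0	yes5	no3	0	rice2013
5	Asclepias syriaca	asterids; lamiids; Gentianales	NC_022796	29093	29432	340	ndhB-1	100	rosids; fabids; Fabales	0	yes4	no1	0	this_study
6	Asclepias syriaca	asterids; lamiids; Gentianales	NC_022797	40124	42206	2083	ndhB-1; rps7; rps12	100	rosids; fabids; Fabales	0	no1	no2	0	this_study
7	Asclepias syriaca	asterids; lamiids; Gentianales	NC_022798	310073	311353	1281	non-coding region	100	rosids; fabids; Fabales	0	no3	yes5	0	this_study
8	Asclepias syriaca	asterids; lamiids; Gentianales	NC_022796	497713	497990	278	ndhD	100	rosids; malvids; Malvales; Malvaceae	0	no1	no2	0	this_study
9	Cucurbita pepo	rosids; fabids; Cucurbitales	NC_014050	252522	253546	1025	cemA; petA	100	asterids; lamiids; Lamiales; Orobanchaceae	0	no1	yes4	1	this_study
10	Cucurbita pepo	rosids; fabids; Cucurbitales	NC_014050	848217	849548	1332	rps7	93	rosids; fabids; Malpighiales; Euphorbiaceae; Acalyphoideae	0	no2	no1	0	this_study
11	Erythranthe guttata	asterids; lamiids; Lamiales	NC_018041	469539	469886	348	rps7	90	rosids; fabids; Fabales; Fabaceae	0	no3	no3	0	this_study
12	Geranium brycei	rosids; malvids; Geraniales	KP974317	47781	49416	1636	rbcL	-	asterids; lamiids; Solanales; Convolvulaceae; Cuscuta	0	no3	no3	1	park2015
13	Geranium brycei	rosids; malvids; Geraniales	KP974313	55290	56417	1128	psaA	-	asterids; lamiids; Solanales; Convolvulaceae; Cuscuta	0	no1	yes5	1	park2015
14	Geranium brycei	rosids; malvids; Geraniales	KP974311	98551	100870	2320	psaB; rps14	-	asterids; lamiids; Solanales; Convolvulaceae; Cuscuta	0	no3	yes5	1	park2015
15	Geranium brycei	rosids; malvids; Geraniales	KP974317	42601	44151	1551	atpB; atpE	-	asterids; lamiids; Solanales; Convolvulaceae; Cuscuta	0	no3	no3	1	park2015
16	Geranium brycei	rosids; malvids; Geraniales	KP974311	343448	347166	3719	rpl2 intron; rpoB 3'; rpoC1 exon 1; ndhJ	-	rosids; fabids; Malpighiales; Euphorbiaceae; Acalyphoideae	0	no3	yes6	0	park2015
17	Geranium brycei	rosids; malvids; Geraniales	KP974311	87980	89010	1031	petB	-	rosids; fabids; Malpighiales; Euphorbiaceae; Acalyphoideae	0	yes6	yes6	0	park2015
18	Geranium brycei	rosids; malvids; Geraniales	KP974317	19534	20704	1171	psbD	-	rosids; fabids; Malpighiales; Euphorbiaceae; Acalyphoideae	0	no1	no3	0	park2015
19	Geranium brycei	rosids; malvids; Geraniales	KP974312	105427	106239	813	matK	-	asterids; lamiids; Gentianales; Rubiaceae; Rubioideae	0	no3	yes6	0	park2015
20	Geranium maderense	rosids; malvids; Geraniales	NC_027000	454189	454564	376	trnA; trnG	98	asterids; lamiids; Lamiales	0	no3	yes4	0	this_study
21	Glycine max	rosids; fabids; Fabales	NC_020455	230204	230895	692	rbcL	-	asterids; lamiids; Gentianales; Apocynaceae	0	yes4	yes4	0	sloan2014
22	Gossypium harknessii	rosids; malvids; Malvales	NC_027406	365728	365950	223	psbD	82	rosids; fabids; Malpighiales; Euphorbiaceae	0	yes4	no3	0	this_study
23	Helianthus annuus	asterids; campanulids; Asterales	NC_023337	107850	108495	646	infA; rps8; rps11	98	rosids; Saxifragales; Penthoraceae	0	no5	yes5	0	this_study
24	Hyoscyamus niger	asterids; lamiids; Solanales	NC_026515	351599	353572	1974	rps12	98	rosids; Rosales; Cannabaceae	0	yes4	yes4	0	this_study
25	Hyoscyamus niger	asterids; lamiids; Solanales	NC_026515	354959	355152	194	non-coding region	99	rosids; Rosales; Cannabaceae	1	yes4	yes4	0	this_study
26	Hyoscyamus niger	asterids; lamiids; Solanales	NC_026515	355156	356418	1263	petB	100	rosids; Rosales; Cannabaceae; Cannabis	1	yes4	yes4	0	this_study
27	Lophophytum mirabile	Santalales	KU992322-KU992380	-	-	245	rpl2	100	rosids; fabids; Fabales; Mimosoideae; Acacia ligulata	1	yes5	yes4	1	sanchezpuerta2017
28	Lophophytum mirabile	Santalales	KU992322-KU992380	-	-	726	rrn23	80	rosids; fabids; Fabales; Mimosoideae; Acacia ligulata	1	no3	yes5	1	sanchezpuerta2017
29	Lophophytum mirabile	Santalales	KU992322-KU992380	-	-	638	psbA	100	rosids; fabids; Fabales; Mimosoideae; Acacia ligulata	1	yes4	yes5	1	sanchezpuerta2017
30	Lophophytum mirabile	Santalales	KU992322-KU992380	-	-	520	rpl16	72	rosids; fabids; Fabales; Mimosoideae	0	no3	no3	1	sanchezpuerta2017
31	Lophophytum mirabile	Santalales	KU992322-KU992380	-	-	673	petG; trnW	76	rosids; fabids; Fabales; Mimosoideae; Acacia ligulata	1	yes5	yes4	1	sanchezpuerta2017
32	Lophophytum mirabile	Santalales	KU992322-KU992380	-	-	269	rbcL	99	rosids; fabids; Fabales; Fabaceae	0	no3	no5	1	sanchezpuerta2017
33	Lophophytum mirabile	Santalales	KU992322-KU992380	-	-	771	rpl2	90	rosids; fabids; Fabales; Fabaceae	0	yes4	no1	1	sanchezpuerta2017
34	Lotus japonicus	rosids; fabids; Fabales	NC_016743	307253	308275	1023	rbcL	-	asterids; lamiids; Solanales; Convolvulaceae; Cuscuta	0	yes4	no3	1	sloan2014
35	Phoenyx dactylifera	Liliopsida; Arecaceae	NC_016740	179688	180534	847	trnI; trnA	-	rosids; fabids; Fagales; Fagaceae	0	no3	no3	0	sloan2014
36	Rhazya stricta	asterids; lamiids; Gentianales	NC_024293	236269	237891	1623	trnI; ycf2	87	asterids; lamiids; Lamiales; Oleaceae; Oleeae; Hesperelaea	1	no3	yes4	0	this_study
37	Salvia miltiorrhiza	asterids; lamiids; Lamiales	NC_023209	209571	209920	350	psbA	100	rosids; fabids; Fabales; Fabaceae	0	yes4	yes5	0	this_study
38	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	1737	psbC; psbD	-	rosids; Vitales; Tetrastigma	1	no1	yes5	1	xi2013
39	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	395	psbA	-	rosids; Vitales; Tetrastigma	1	no1	no3	1	xi2013
40	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	504	ndhB	-	rosids; Vitales; Tetrastigma	0	yes4	no3	1	xi2013
41	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	477	atpB	-	rosids; Vitales; Tetrastigma	1	no1	yes5	1	xi2013
42	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	3703	rpoC1; rpoC2	-	rosids; Vitales; Tetrastigma	0	yes4	yes4	1	xi2013
43	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	2595	rps12	-	rosids; Vitales	0	NA	yes5	1	xi2013
44	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	436	rbcL	-	rosids; Vitales	0	no3	no3	1	xi2013
45	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	360	psaB	-	rosids; Vitales; Tetrastigma	1	no1	no3	1	xi2013
46	Sapria himalayana	rosids; fabids; Malpighiales	-	-	-	457	atpA	-	asterids; campanulids; Apiales; Daucus	0	no3	no1	1	xi2013
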