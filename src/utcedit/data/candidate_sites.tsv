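s_no	position	reads_d12	reads_d20	gene_id	description
1	3412532	56	0	AT2G07715	Ribosomal Proteins L2, RNA binding domain
2	8544440	34	0	AT4G14940	Amine oxidase
3	26898977	2	0	AT5G67411	GRAS family transcription factor
4	8297931	4	0	AT1G23380	KNOTTED1-like homeobox gene 6
5	14657330	14	0	AT4G29950	Ypt/Rab-GAP domain of gyp1p superfamily protein
6	3392826	107	16	AT2G07709	-
7	362386	175	44	ATMG01390	-
8	7191444	105	197	AT2G16586	Unknown
9	3061212	498	2	AT4G06477	-
10	9226791	28	69	AT4G16330	2-oxoglutarate (2OG) and Fe(II)-dependent oxygenase superfamily protein
11	5816271	12	6	AT3G17050	-
12	9255546	268	99	AT4G16380	Heavy metal transport/detoxification superfamily protein
13	14198871	647	240	AT3G41768	-
14	16918673	55	46	AT5G42320	Zn-dependent exopeptidases superfamily protein
15	17708862	0	21	AT3G47965	Unknown
16	24989428	27	0	AT5G62220	glycosyltransferase 18
17	21320395	0	12	AT5G52530	dentin sialophosphoprotein-related
18	2848835	146	86	AT5G08740	NAD(P)H dehydrogenase C1
19	15546833	13	0	AT4G32190	Myosin heavy chain-related protein
20	3392918	144	14	AT2G07709	-
21	21319578	0	5	AT5G52530	dentin sialophosphoprotein-related
22	21077241	0	2	AT1G56290	CwfJ-like family protein
23	7622202	0	2	AT4G13070	RNA-binding CRS1/YhbY (CRM) domain protein
24	17692876	29	0	AT5G43970	translocase of outer membrane 22-V
25	10266697	46	6	AT1G29340	plant U-box 17
26	7869982	17	0	AT5G23380	Protein of unknown function (DUF789)
27	7836325	19	0	AT1G22190	Integrase-type DNA-binding superfamily protein
28	19998466	36	0	AT3G54000	Unknown
29	603074	13	5	AT5G02670	Unknown
30	22561577	0	2	AT3G60970	multidrug resistance-associated protein 15
31	6025041	0	27	AT4G09520	Cofactor-independent phosphoglycerate mutase
32	909133	0	2	AT4G02070	MUTS homolog 6
33	7797368	0	4	AT4G13420	high affinity K+ transporter 5
34	8662474	0	3	AT4G15180	SET domain protein 2
35	12669828	0	2	AT4G24530	O-fucosyltransferase family protein
36	15653919	0	2	AT4G32430	Pentatricopeptide repeat (PPR) superfamily protein
37	5075516	0	2	AT2G12490	-
38	17587422	0	2	AT2G42200	squamosa promoter binding protein-like 9
39	17958701	0	2	AT2G43200	S-adenosyl-L-methionine-dependent methyltransferases superfamily protein
40	526197	0	5	AT3G02515	-
41	20795012	69	64	AT3G56040	UDP-glucose pyrophosphorylase 3
42	3264804	0	2	AT5G10370	helicase domain-containing protein/IBR domain-containing protein/zinc finger protein-related
43	9633752	0	2	AT5G27330	Prefoldin chaperone subunit family protein
44	12108844	0	9	AT5G32481	-
45	15644809	0	4	AT5G39090	HXXXD-type acyl-transferase family protein
46	3332097	0	2	AT1G10160	-
47	3564739	0	2	AT1G10720	BSD domain-containing protein
48	9825469	0	6	AT1G28130	Auxin-responsive GH3 family protein
49	9997031	0	2	AT1G28440	HAESA-like 1
50	4006628	0	13	AT5G12370	exocyst complex component sec10
51	5097198	0	5	AT2G12505	-
52	11465954	0	11	AT1G31930	extra-large GTP-binding protein 3
53	7014676	0	2	AT3G20087	N/A
54	15766171	0	2	AT2G37585	Core-2/I-branching beta-1,6-N-acetylglucosaminyltransferase family protein
55	7191297	249	171	AT2G16586	Unknown
56	17908527	0	2	AT1G48450	Protein of unknown function (DUF760)
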