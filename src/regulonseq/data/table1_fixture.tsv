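peak_id	locus_id	cyst_regulated	gene_name	strand	distance	role	function	log2fc	site_seq	cog
7	RC1_1074	yes	coxM	+		in_operon	carbon monoxide dehydrogenase	-1.81138	CGTTCTCACCTTCACG	C
7	RC1_1075	yes	coxL	-	-605	first_in_operon	carbon monoxide dehydrogenase	-1.73844	CGTTCTCACCTTCACG	C
10	RC1_1588	yes	alkJ	+	-258	single	alcohol dehydrogenase	-1.72171	CGTGACCGCCGTCACA	E
14	RC1_2001	yes		+	-723	single	RNA polymerase sigma-70 factor	-6.61303	CTTTCGATGGCTCTCA	K
6	RC1_0849	yes		+	-195	single	transcriptional regulator, LuxR family protein	-2.03622	TGTTGTCGGCATCAAG	K
15	RC1_2169	yes		-	-92	single	RNA polymerase sigma-32 factor	-1.55582	CGCAAGGCGCAGCGCC	K
18	RC1_2981	no	chrR	+	-199	single	transcriptional activator ChrR	1.36715	TGTGATCCATTTTGCG	K
13	RC1_1927	no		+	-479	single	CRISPR-associated protein	-1.37779	TTTGCCCACCCACAGA	L
24	RC1_3483	no		+		in_operon	CRISPR-associated protein	-3.95202	TCTGAATGATATCAAG	L
24	RC1_3484	no		+		in_operon	CRISPR-associated RAMP protein	-3.95202	TCTGAATGATATCAAG	L
24	RC1_3482	no		+	-661	first_in_operon	CRISPR-associated protein	-3.68884	TCTGAATGATATCAAG	L
28	RC1_4002	yes	wcaJ	-	-174	single	colanic biosynthesis UDP-glucose lipid carrier transferase	-2.9087	TTTGTGACGCTTAGAA	M
16	RC1_2533	yes	exoP	-	36	single	succinoglycan biosynthesis transport protein ExoP	-2.20703	CTCGCGGAAGGGAATG	M
9	RC1_1393	no	flgI	+	-270	first_in_operon	flagellar P-ring protein FlgI	-2.13001	CCAGATATTGGTAACA	N
8	RC1_1261	no	frnE	+	-139	single	DSBA-like thioredoxin family protein	2.02091	CGTCACGTAGGTTTCG	Q
7	RC1_1072	yes	coxE	+		in_operon	CoxE protein	-1.81138	CGTTCTCACCTTCACG	R
7	RC1_1073	yes	coxD	+		in_operon	carbon monoxide dehydrogenase D protein	-1.81138	CGTTCTCACCTTCACG	R
14	RC1_1997	yes		+		in_operon	R body protein	-9.38585	CTTTCGATGGCTCTCA	S
14	RC1_1998	yes		+		in_operon	R body protein	-9.35414	CTTTCGATGGCTCTCA	S
14	RC1_1996	yes		+		in_operon	R body protein	-8.84511	CTTTCGATGGCTCTCA	S
14	RC1_1994	yes		+		in_operon	R body protein	-8.34157	CTTTCGATGGCTCTCA	S
14	RC1_1993	yes		+		in_operon	R body protein	-8.21744	CTTTCGATGGCTCTCA	S
14	RC1_1995	yes		+		in_operon	R body protein	-7.64522	CTTTCGATGGCTCTCA	S
25	RC1_3786	no	gcyB	+		in_operon	hypothetical protein	-6.4452	TGTGAAGCAGTTCACA	S
25	RC1_3787	no	gcyC	+		in_operon	hypothetical protein	-6.08831	TGTGAAGCAGTTCACA	S
5	RC1_0834	yes		+	-202	single	hypothetical protein	-2.6779	GATAAAGTGGCGCACA	S
9	RC1_1394	no	cheL	+		in_operon	chemotactic signal-response protein CheL	-2.13001	CCAGATATTGGTAACA	S
12	RC1_1693	yes		-	-226	single	phasin family protein	-1.93541	CGCACCGTCCCGCAGA	S
24	RC1_3478	no		+	-161	single	hypothetical protein	-1.74953	GGCAAATAACAACAAA	S
2	RC1_0093	no		+	-204	single	phage protein Gp37	-1.4638	CGCGAAGATCGGCGCA	S
6	RC1_0849	yes		+	-195	single	transcriptional regulator, LuxR family protein	-2.03622	TGTTGTCGGCATCAAG	T
20	RC1_3006	no	pleC	+	-90	single	non-motile and phage-resistance protein	1.39601	GGTGCCCCGGTTCTCC	T
27	RC1_3832	no		-	-118	single	methyl-accepting chemotaxis protein	2.05864	CTTAAAGGGGGGTAAA	T
1	RC1_0024	yes		+	-52	single	ABC transporter ATP-binding protein	-2.84109	GGCGGTCCCGGTCACC	V
25	RC1_3785	no		+	-188	first_in_operon	hypothetical protein	-8.90946	TGTGAAGCAGTTCACA	-
14	RC1_2000	yes		-	-96	first_in_operon	hypothetical protein	-6.52071	CTTTCGATGGCTCTCA	-
25	RC1_3784	no		-	-43	single	hypothetical protein	-6.24446	TGTGAAGCAGTTCACA	-
14	RC1_1999	yes		+		in_operon	R body protein	-5.42666	CTTTCGATGGCTCTCA	-
17	RC1_2730	yes		-	-855	single	hypothetical protein	-4.97489	TTTGAAGTTCCCCCCA	-
4	RC1_0632	no		-	-28	single	hypothetical protein	-3.29529	TGTACAGCACCTCGAA	-
22	RC1_3373	yes	ecnAB	-	-145	single	ecnAB; entericidin EcnAB family protein	-2.03569	GGTGACCTTCCTGGGG	-
11	RC1_1636	yes		+	-79	single	hypothetical protein	-1.47009	CGTGCCGCCCGGAAAG	-
3	RC1_0163	no		+	-415	single	hypothetical protein	1.33965	TTCAAAATACCGCGAA	-
19	RC1_2985	no		+	-651	single	hypothetical protein	1.5141	CTTGTAGAGCTTCATG	-
21	RC1_3208	no		+	-158	single	ABC transporter substrate-binding protein	1.60476	CGCGACGGGGGGAACG	-
26	RC1_3822	yes		-	-146	single	putative Ig domain-containing protein	2.87758	TTTGATAAAATCCAAT	-
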