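strain	parent	position	mutation	coding_change	locus
Fast_1a	WT	4176719	G>A	rpoC(R481H)	rpoC
Fast_1b	WT	1749977	G>A	pykF(C8Y)	pykF
Fast_2a	WT	1750065	delT	pykF(H37fs)	pykF
Fast_2b	WT	1750065	delT	pykF(H37fs)	pykF
Fast_2b	WT	608104	G>T	fepA(-154)/fes(-89)	fepA-fes
Fast_3a	WT	1759946	IS5(+)	pykF(-3::IS5)	pykF
Fast_3b	WT	1759946	IS5(+)	pykF(-3::IS5)	pykF
Fast_4a	WT	4174281	A>C	rpoB(T1037P)	rpoB
Fast_4b	WT	4174281	A>C	rpoB(T1037P)	rpoB
Fast_5a	WT	1750309	IS5(+)	pykF(V119::IS5)	pykF
Fast_5a	WT	647643	G>T	citC(-218)/citA(-161)	citC-citA
Fast_5b	WT	1750309	IS5(+)	pykF(V119::IS5)	pykF
Fast_6a	WT	4178881	G>A	rpoC(E1202K)	rpoC
Fast_6b	WT	4178881	G>A	rpoC(E1202K)	rpoC
Fast_6b	WT	2471573	C>T	dsdX(S83F)	dsdX
zwf_sup1	zwf	4178209	C>A	rpoC(R978S)	rpoC
zwf_sup1	zwf	1301660	IS5(+)	clsA(L414::IS5)	clsA
zwf_sup2	zwf	4171264	A>G	rpoB(Q31R)	rpoB
zwf_sup2	zwf	766917	IS5(+)	cydA(L2::IS5)	cydA
zwf_sup3	zwf	1107358	C>T	opgH(A347V)	opgH
zwf_sup3	zwf	4172719	A>G	rpoB(D516G)	rpoB
zwf_sup4	zwf	155376	C>T	pcnB(D80N)	pcnB
zwf_sup4	zwf	4172719	A>G	rpoB(D516G)	rpoB
ppk_sup1	ppk	4178896	(TAGAACGTG)1->2	rpoC(G1207VERG)	rpoC
ppk_sup2	ppk	4178210	G>C	rpoC(R978P)	rpoC
ppk_sup3	ppk	4173134	C>G	rpoB(D654E)	rpoB
dapF_sup1	dapF	4174048	A>G	rpoB(D959G)	rpoB
dapF_sup1	dapF	928451	C>A	lrp(T134N)	lrp
dapF_sup2	dapF	4173309	G>T	rpoB(G713C)	rpoB
dapF_sup2	dapF	928451	C>A	lrp(T134N)	lrp
dapF_sup3	dapF	3809168	delA	pyrE(-40)	pyrE
dapF_sup3	dapF	928332	T>G	lrp(N94K)	lrp
entC_sup1	entC	1750786	A>C	pykF(T278P)	pykF
entC_sup1	entC	2374180	G>A	menF(-58)	menF
entC_sup2	entC	2374177	G>A	menF(-55)	menF
entC_sup2	entC	4172731	C>T	rpoB(P520L)	rpoB
entC_sup3	entC	2374180	G>A	menF(-58)	menF
entC_sup3	entC	4178500	C>T	rpoC(R1075C)	rpoC
dgk_sup1	dgk	4178500	C>T	rpoC(R1075C)	rpoC
dgk_sup2	dgk	4172748	C>T	rpoB(H526Y)	rpoB
dgk_sup3	dgk	3310740	A>T	nusA(I49N)	nusA
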