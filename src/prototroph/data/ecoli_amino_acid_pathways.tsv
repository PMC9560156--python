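variant_id	amino_acid	step_index	step_id	ec_options	substrate	product	gene_symbols
val_ec1	Val	1	ahas	2.2.1.6	pyruvate	2-acetolactate	ilvB;ilvN
val_ec1	Val	2	kari	1.1.1.86	2-acetolactate	2,3-dihydroxy-isovalerate	ilvC
val_ec1	Val	3	dhad	4.2.1.9	2,3-dihydroxy-isovalerate	2-oxoisovalerate	ilvD
val_ec1	Val	4	bcat	2.6.1.42	2-oxoisovalerate	valine	ilvE
ile_ec1	Ile	1	td	4.3.1.19	threonine	2-oxobutanoate	ilvA
ile_ec1	Ile	2	ahas	2.2.1.6	2-oxobutanoate	2-aceto-2-hydroxybutanoate	ilvB;ilvN
ile_ec1	Ile	3	kari	1.1.1.86	2-aceto-2-hydroxybutanoate	2,3-dihydroxy-3-methylvalerate	ilvC
ile_ec1	Ile	4	dhad	4.2.1.9	2,3-dihydroxy-3-methylvalerate	2-oxo-3-methylvalerate	ilvD
ile_ec1	Ile	5	bcat	2.6.1.42	2-oxo-3-methylvalerate	isoleucine	ilvE
leu_ec1	Leu	1	ipms	2.3.3.13	2-oxoisovalerate	2-isopropylmalate	leuA
leu_ec1	Leu	2	ipmi	4.2.1.33	2-isopropylmalate	3-isopropylmalate	leuC;leuD
leu_ec1	Leu	3	ipmd	1.1.1.85	3-isopropylmalate	2-oxoisocaproate	leuB
leu_ec1	Leu	4	bcat	2.6.1.42	2-oxoisocaproate	leucine	ilvE
lys_ec1	Lys	1	ask	2.7.2.4	aspartate	4-phospho-aspartate	lysC
lys_ec1	Lys	2	asd	1.2.1.11	4-phospho-aspartate	aspartate-4-semialdehyde	asd
lys_ec1	Lys	3	dhdps	4.3.3.7	aspartate-4-semialdehyde	2,3-dihydrodipicolinate	dapA
lys_ec1	Lys	4	dhdpr	1.17.1.8	2,3-dihydrodipicolinate	tetrahydrodipicolinate	dapB
lys_ec1	Lys	5	thdps	2.3.1.117	tetrahydrodipicolinate	N-succinyl-2-amino-6-oxopimelate	dapD
lys_ec1	Lys	6	sdapat	2.6.1.17	N-succinyl-2-amino-6-oxopimelate	N-succinyl-LL-diaminopimelate	argD
lys_ec1	Lys	7	sdapds	3.5.1.18	N-succinyl-LL-diaminopimelate	LL-diaminopimelate	dapE
lys_ec1	Lys	8	dapep	5.1.1.7	LL-diaminopimelate	meso-diaminopimelate	dapF
lys_ec1	Lys	9	dapdc	4.1.1.20	meso-diaminopimelate	lysine	lysA
met_ec1	Met	1	ask	2.7.2.4	aspartate	4-phospho-aspartate	metL;lysC
met_ec1	Met	2	asd	1.2.1.11	4-phospho-aspartate	aspartate-4-semialdehyde	asd
met_ec1	Met	3	hsd	1.1.1.3	aspartate-4-semialdehyde	homoserine	metL
met_ec1	Met	4	hst	2.3.1.46	homoserine	O-succinylhomoserine	metA
met_ec1	Met	5	cgs	2.5.1.48	O-succinylhomoserine	cystathionine	metB
met_ec1	Met	6	cbl	4.4.1.13	cystathionine	homocysteine	metC
met_ec1	Met	7	ms	2.1.1.13;2.1.1.14	homocysteine	methionine	metE;metH
thr_ec1	Thr	1	ask	2.7.2.4	aspartate	4-phospho-aspartate	thrA
thr_ec1	Thr	2	asd	1.2.1.11	4-phospho-aspartate	aspartate-4-semialdehyde	asd
thr_ec1	Thr	3	hsd	1.1.1.3	aspartate-4-semialdehyde	homoserine	thrA
thr_ec1	Thr	4	hsk	2.7.1.39	homoserine	O-phospho-homoserine	thrB
thr_ec1	Thr	5	ts	4.2.3.1	O-phospho-homoserine	threonine	thrC
phe_ec1	Phe	1	dahps	2.5.1.54	PEP-and-erythrose-4-phosphate	DAHP	aroF;aroG;aroH
phe_ec1	Phe	2	dhqs	4.2.3.4	DAHP	3-dehydroquinate	aroB
phe_ec1	Phe	3	dhqd	4.2.1.10	3-dehydroquinate	3-dehydroshikimate	aroD
phe_ec1	Phe	4	sdh	1.1.1.25	3-dehydroshikimate	shikimate	aroE
phe_ec1	Phe	5	sk	2.7.1.71	shikimate	shikimate-3-phosphate	aroK;aroL
phe_ec1	Phe	6	epsps	2.5.1.19	shikimate-3-phosphate	5-enolpyruvyl-shikimate-3-phosphate	aroA
phe_ec1	Phe	7	cs	4.2.3.5	5-enolpyruvyl-shikimate-3-phosphate	chorismate	aroC
phe_ec1	Phe	8	cm	5.4.99.5	chorismate	prephenate	pheA
phe_ec1	Phe	9	pdt	4.2.1.51	prephenate	phenylpyruvate	pheA
phe_ec1	Phe	10	arat	2.6.1.57	phenylpyruvate	phenylalanine	tyrB
trp_ec1	Trp	1	dahps	2.5.1.54	PEP-and-erythrose-4-phosphate	DAHP	aroF;aroG;aroH
trp_ec1	Trp	2	dhqs	4.2.3.4	DAHP	3-dehydroquinate	aroB
trp_ec1	Trp	3	dhqd	4.2.1.10	3-dehydroquinate	3-dehydroshikimate	aroD
trp_ec1	Trp	4	sdh	1.1.1.25	3-dehydroshikimate	shikimate	aroE
trp_ec1	Trp	5	sk	2.7.1.71	shikimate	shikimate-3-phosphate	aroK;aroL
trp_ec1	Trp	6	epsps	2.5.1.19	shikimate-3-phosphate	5-enolpyruvyl-shikimate-3-phosphate	aroA
trp_ec1	Trp	7	cs	4.2.3.5	5-enolpyruvyl-shikimate-3-phosphate	chorismate	aroC
trp_ec1	Trp	8	as	4.1.3.27	chorismate	anthranilate	trpE;trpD
trp_ec1	Trp	9	aprt	2.4.2.18	anthranilate	N-phosphoribosyl-anthranilate	trpD
trp_ec1	Trp	10	prai	5.3.1.24	N-phosphoribosyl-anthranilate	CdRP	trpC
trp_ec1	Trp	11	igps	4.1.1.48	CdRP	indole-3-glycerol-phosphate	trpC
trp_ec1	Trp	12	trps	4.2.1.20	indole-3-glycerol-phosphate	tryptophan	trpA;trpB
his_ec1	His	1	atpprt	2.4.2.17	PRPP-and-ATP	phosphoribosyl-ATP	hisG
his_ec1	His	2	prapp	3.6.1.31	phosphoribosyl-ATP	phosphoribosyl-AMP	hisE
his_ec1	His	3	prachy	3.5.4.19	phosphoribosyl-AMP	ProFAR	hisI
his_ec1	His	4	profari	5.3.1.16	ProFAR	PRFAR	hisA
his_ec1	His	5	igpsyn	4.3.2.10	PRFAR	imidazole-glycerol-phosphate	hisF;hisH
his_ec1	His	6	igpd	4.2.1.19	imidazole-glycerol-phosphate	imidazole-acetol-phosphate	hisB
his_ec1	His	7	hpat	2.6.1.9	imidazole-acetol-phosphate	histidinol-phosphate	hisC
his_ec1	His	8	hpp	3.1.3.15	histidinol-phosphate	histidinol	hisB
his_ec1	His	9	hdh	1.1.1.23	histidinol	histidine	hisD
ala_ec1	Ala	1	alat	2.6.1.2	pyruvate	alanine	alaA;alaC
arg_ec1	Arg	1	nags	2.3.1.1	glutamate	N-acetylglutamate	argA
arg_ec1	Arg	2	nagk	2.7.2.8	N-acetylglutamate	N-acetylglutamyl-phosphate	argB
arg_ec1	Arg	3	nagsd	1.2.1.38	N-acetylglutamyl-phosphate	N-acetylglutamate-semialdehyde	argC
arg_ec1	Arg	4	acoat	2.6.1.11	N-acetylglutamate-semialdehyde	N-acetylornithine	argD
arg_ec1	Arg	5	aod	3.5.1.16	N-acetylornithine	ornithine	argE
arg_ec1	Arg	6	otc	2.1.3.3	ornithine	citrulline	argF;argI
arg_ec1	Arg	7	ass	6.3.4.5	citrulline	argininosuccinate	argG
arg_ec1	Arg	8	asl	4.3.2.1	argininosuccinate	arginine	argH
asp_ec1	Asp	1	aspat	2.6.1.1	oxaloacetate	aspartate	aspC
asn_ec1	Asn	1	asns	6.3.5.4;6.3.1.1	aspartate	asparagine	asnB;asnA
glu_ec1	Glu	1	gdh	1.4.1.4;1.4.1.3;1.4.1.2	2-oxoglutarate	glutamate	gdhA
gln_ec1	Gln	1	gs	6.3.1.2	glutamate	glutamine	glnA
gly_ec1	Gly	1	shmt	2.1.2.1	serine	glycine	glyA
ser_ec1	Ser	1	pgdh	1.1.1.95	3-phosphoglycerate	3-phosphohydroxypyruvate	serA
ser_ec1	Ser	2	psat	2.6.1.52	3-phosphohydroxypyruvate	3-phosphoserine	serC
ser_ec1	Ser	3	psp	3.1.3.3	3-phosphoserine	serine	serB
cys_ec1	Cys	1	sat	2.3.1.30	serine	O-acetylserine	cysE
cys_ec1	Cys	2	oass	2.5.1.47	O-acetylserine	cysteine	cysK;cysM
cys_ec2	Cys	1	cbs	4.2.1.22	homocysteine-and-serine	cystathionine	CBS
cys_ec2	Cys	2	cgl	4.4.1.1	cystathionine	cysteine	CTH
pro_ec1	Pro	1	g5k	2.7.2.11	glutamate	glutamate-5-phosphate	proB
pro_ec1	Pro	2	g5sd	1.2.1.41	glutamate-5-phosphate	glutamate-5-semialdehyde	proA
pro_ec1	Pro	3	p5cr	1.5.1.2	glutamate-5-semialdehyde	proline	proC
tyr_ec1	Tyr	1	cm	5.4.99.5	chorismate	prephenate	tyrA
tyr_ec1	Tyr	2	pdh	1.3.1.12	prephenate	4-hydroxyphenylpyruvate	tyrA
tyr_ec1	Tyr	3	arat	2.6.1.57	4-hydroxyphenylpyruvate	tyrosine	tyrB
tyr_ec2	Tyr	1	pah	1.14.16.1	phenylalanine	tyrosine	PAH
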