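chrom	pos	ref	alt	gene	region	effect	hgvs_c	hgvs_p	dbsnp_id	af_1000g	af_esp	af_exac	sift	pp2_hvar	pp2_hdiv
1	145368473	G	C	NBPF9	exonic	unknown	./.	./.	rs1043749	.	.	.	./.	./.	./.
1	145368518	C	T	NBPF9	exonic	unknown	./.	./.	rs61813437	.	.	.	./.	./.	./.
11	1213275	G	A	MUC5AC	exonic	unknown	./.	./.	rs71251383	.	.	.	./.	./.	./.
12	53343033	G	A	KRT18	exonic	missense SNV	c.G76A	p.A26T	rs78514003	.	.	.	0.549, T	0.003, B	0.005, B
12	53343036	C	T	KRT18	exonic	missense SNV	c.C79T	p.R27W	rs77825282	.	.	.	0.032, D	0.001, B	0.001, B
12	53343040	C	A	KRT18	exonic	missense SNV	c.C83A	p.P28Q	rs74379840	.	.	.	0.098, T	0.716, P	0.982, D
12	53343051	G	T	KRT18	exonic	missense SNV	c.G94T	p.A32S	rs74953757	.	.	.	0.171, T	0.688, P	0.91, P
12	53343059	C	A	KRT18	exonic	missense SNV	c.C102A	p.S34R	rs78343594	.	.	.	0.001, D	0.081, B	0.087, B
12	53343069	G	T	KRT18	exonic	missense SNV	c.G112T	p.G38C	rs77999286	.	.	.	0.009, D	0.923, D	0.988, D
12	53343084	G	C	KRT18	exonic	missense SNV	c.G127C	p.G43R	rs75441140	.	.	.	0.001, D	0.554, P	0.949, P
12	53343099	G	A	KRT18	exonic	missense SNV	c.G142A	p.V48M	.	.	.	.	0.147, T	0.11, B	0.642, P
12	53343105	C	T	KRT18	exonic	missense SNV	c.C148T	p.R50C	rs78479490	.	.	.	0.299, T	0.004, B	0.003, B
12	53343124	G	A	KRT18	exonic	missense SNV	c.G167A	p.G56D	rs76183244	.	.	.	0.054, T	0.015, B	0.017, B
12	53343148	C	G	KRT18	exonic	missense SNV	c.C191G	p.A64G	.	.	.	.	0.718, T	0.009, B	0.028, B
12	53343158	A	G	KRT18	exonic	missense SNV	c.A201G	p.I67M	rs77364359	.	.	.	0.493, T	0.0, B	0.0, B
13	25670877	G	A	PABPC3	exonic	missense SNV	c.G541A	p.A181T	rs112107735	.	.	.	0.042, D	0.253, B	0.627, P
13	25670907	C	A	PABPC3	exonic	missense SNV	c.C571A	p.P191T	rs76264750	.	.	.	1.0, T	0.0, B	0.0, B
13	25670919	A	G	PABPC3	exonic	missense SNV	c.A583G	p.I195V	rs76861216	.	.	.	1.0, T	0.023, B	0.005, B
13	25670953	G	A	PABPC3	exonic	missense SNV	c.G617A	p.R206H	rs74040928	.	.	.	0.089, T	0.043, B	0.114, B
13	25670955	C	T	PABPC3	exonic	missense SNV	c.C619T	p.L207F	rs79397892	.	.	.	0.192, T	0.978, D	0.999, D
13	25670988	T	G	PABPC3	exonic	missense SNV	c.T652G	p.L218V	rs74564616	.	.	.	0.287, T	0.041, B	0.027, B
13	25671027	A	G	PABPC3	exonic	missense SNV	c.A691G	p.K231E	rs78826513	.	.	.	0.001, D	0.953, D	0.995, D
13	25671172	C	A	PABPC3	exonic	missense SNV	c.C836A	p.T279K	rs79593984	.	.	.	1.0, T	0.0, B	0.0, B
13	25671214	T	G	PABPC3	exonic	missense SNV	c.T878G	p.V293G	rs201081849	.	.	.	1.0, T	0.0, B	0.0, B
1	17085999	CCCCG	C	MST1L	exonic	frameshift deletion	./.	./.	rs59375146	.	.	.	./.	./.	./.
9	95237024	CTCATCA	CTCATCATCA	ASPN	exonic	Non-frameshift deletion	./.	./.	.	.	.	.	./.	./.	./.
9	95237024	CTCATCA	CTCA	ASPN	exonic	Non-frameshift deletion	./.	./.	.	.	.	.	./.	./.	./.
12	7045891	ACAGCAGCAGCAGCAGAGCAGCAGCAG	ACAGCAGCAGCAG	ATN1	exonic	Non-frameshift insertion	./.	./.	rs797045323	.	.	.	./.	./.	./.
12	7045891	ACAGCAGCAGCAGCAGCAGCAGCAGCAG	ACAGCAGCAGCAGCAGCAGCAGCAGCAGCAGCAG	ATN1	exonic	Non-frameshift insertion	./.	./.	rs797045323	.	.	.	./.	./.	./.
13	25671149	ACGG	A	PABPC3	exonic	Non-frameshift deletion	./.	./.	rs368285293	.	.	.	./.	./.	./.
13	78272267	T	TGG	SLAIN1	exonic	frameshift insertion	./.	./.	rs201380414	.	.	.	./.	./.	./.
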