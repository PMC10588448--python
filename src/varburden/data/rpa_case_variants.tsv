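COHORT	POSITION	SAMPLE	DIAGNOSIS	GENE	DOMAIN	CDNA	PROTEIN	CONSEQUENCE	ANCESTRY	AF	ANCESTRY_AF	CADD	REVEL	ACMG	DDG
HEM	1747265	SJBALL032225	BALL	RPA1	F	c.A136G	p.M46V	missense	AMR	0.0013%	0.0029%	22.2	0.28	VUS	unavailable
HEM	1747266	SJALL041240	BALL	RPA1	F	c.T137C	p.M46T	missense	NFE	novel	novel	25.2	0.456	VUS	1.9
HEM	1747283	SJALL041360	BALL	RPA1	F	c.155_156del	p.L53Ifs*53	frameshift_indel	NFE	0.0008%	0.0020%	NA	NA	VUS	unavailable
HEM	1747879	SJHL042034	HL	RPA1	F	c.G171A	p.M57I	missense	NFE	novel	novel	28	0.492	VUS	-0.2
HEM	1747882	SJCBF147	AML	RPA1	F	c.G174C	p.L58F	missense	NFE	0.0009%	0.0010%	25.2	0.489	VUS	1.2
HEM	1780546	SJTALL021675	TALL	RPA1	A	c.C628T	p.R210C	missense	Other	0.0038%	novel	35	0.594	VUS	0.6
HEM	1782352	SJBALL020994	BALL	RPA1	A	c.C756G	p.N252K	missense	Other	0.0063%	0.0178%	26.6	0.267	VUS	0.2
HEM	1782605	SJAML030416	AML	RPA1	A	c.G856T	p.V286F	missense	Other	0.0097%	0.0149%	33	0.373	VUS	0.6
HEM	1782605	SJAML031075	AML (AMKL)	RPA1	A	c.G856A	p.V286I	missense	AMR	0.0410%	novel	16.3	0.373	VUS	0.6
HEM	1782605	SJAML032052	AML (AMML)	RPA1	A	c.G856A	p.V286I	missense	NFE	0.0410%	0.0286%	16.3	0.373	VUS	0.6
HEM	1782605	SJAML032355	AML (AMML)	RPA1	A	c.G856A	p.V286I	missense	NFE	0.0410%	0.0286%	16.3	0.373	VUS	0.6
HEM	1782605	SJALL016427	BALL	RPA1	A	c.G856T	p.V286F	missense	NFE	0.0097%	0.0203%	33	0.373	VUS	0.6
HEM	1782983	SJALL041859	BALL	RPA1	B	c.G1082T	p.W361L	missense	NFE	0.0008%	0.0019%	32	0.752	VUS	2.2
HEM	1783867	SJHL041557	HL	RPA1	B	c.G1123A	p.V375M	missense	NFE	0.0021%	0.0049%	28.6	0.413	VUS	1.2
HEM	1783909	SJTALL022093	TALL	RPA1	B	c.C1165T	p.R389W	missense	AMR	0.1763%	0.0028%	35	0.319	VUS	-0.9
HEM	1783909	SJBALL001702	BALL	RPA1	B	c.C1165T	p.R389W	missense	NFE	0.1763%	0.0736%	35	0.319	VUS	-0.9
HEM	1783909	SJALL015269	TALL	RPA1	B	c.C1165T	p.R389W	missense	NFE	0.1763%	0.0736%	35	0.319	VUS	-0.9
HEM	1783909	SJBALL032592	BALL	RPA1	B	c.C1165T	p.R389W	missense	NFE	0.1763%	0.0736%	35	0.319	VUS	-0.9
HEM	1787123	SJNHL042753	NHL	RPA1	B	c.A1259T	p.Q420L	missense	NFE	0.0019%	0.0042%	22	0.16	VUS	unavailable
HEM	1787161	SJNHL042070	NHL	RPA1	coding, non DBD	c.G1297A	p.G433S	missense	AFR	0.0157%	0.0508%	23.5	0.218	VUS	unavailable
HEM	1787173	SJHL042469	HL	RPA1	C	c.G1309A	p.G437R	missense	AFR	0.0134%	0.1397%	24.4	0.286	VUS	unavailable
HEM	1792053	SJALL018944	BALL	RPA1	C	c.A1459G	p.N487D	missense	NFE	novel	novel	28.6	0.564	VUS	0.2
HEM	1792111	SJPHALL020033	BALL	RPA1	C	c.A1517T	p.E506V	missense	AMR	0.0034%	novel	32	0.387	VUS	-0.6
HEM	1792111	SJALL015640	TALL	RPA1	C	c.A1517T	p.E506V	missense	AFR	0.0034%	0.0381%	32	0.387	VUS	-0.6
HEM	1792132	SJERG020054	BALL	RPA1	C	c.G1538A	p.R513H	missense	NFE	0.0164%	0.0331%	35	0.535	VUS	0.4
HEM	1792132	SJHL019322	HL	RPA1	C	c.G1538A	p.R513H	missense	NFE	0.0164%	0.0331%	35	0.535	VUS	0.4
HEM	1795196	SJALL041325	BALL	RPA1	C	c.G1621A	p.G541R	missense	NFE	novel	novel	26.1	0.591	VUS	0.1
HEM	1795196	SJNHL018781	NHL	RPA1	C	c.G1621A	p.G541R	missense	NFE	novel	novel	26.1	0.591	VUS	0.1
HEM	1800399	SJALL018992	BALL	RPA1	C	c.T1781G	p.V594G	missense	NFE	0.0011%	0.0013%	26.5	0.569	VUS	3.3
ST	1747265	SJNBL017162	NBL	RPA1	F	c.A136G	p.M46V	missense	NFE	0.0013%	0.0010%	22.2	0.28	VUS	0.1
ST	1756468	SJRHB032408	Sarcoma (RMS)	RPA1	coding, non DBD	c.G346A	p.V116M	missense	AMR	novel	novel	23.4	0.151	VUS	0.6
ST	1779063	SJWLM019906	WT	RPA1	A	c.C563T	p.A188V	missense	NFE	0.0161%	0.0078%	23.7	0.136	VUS	-0.4
ST	1780603	SJNBL030203	NBL	RPA1	A	c.G685A	p.E229K	missense	AFR	0.0004%	novel	31	0.227	VUS	0
ST	1782605	SJSTS019601	MEL	RPA1	A	c.G856A	p.V286I	missense	NFE	0.0403%	0.0254%	16.32	0.206	VUS	unavailable
ST	1782605	SJMEL031366	Sarcoma (RMS)	RPA1	A	c.G856A	p.V286I	missense	NFE	0.0403%	0.0254%	16.32	0.206	VUS	0.1
ST	1782605	SJRHB000026	Sarcoma (synovial)	RPA1	A	c.G856A	p.V286I	missense	NFE	0.0403%	0.0254%	16.32	0.206	VUS	-0.2
ST	1782611	SJGCT019774	GCT	RPA1	A	c.C862T	p.P288S	missense	AFR	novel	novel	31	0.367	VUS	0.4
ST	1783909	SJRB030058	RB	RPA1	B	c.C1165T	p.R389W	missense	NFE	0.1763%	0.0736%	35	0.319	VUS	-0.6
ST	1783972	SJOS040162	Sarcoma (OS)	RPA1	B	c.A1228G	p.K410E	missense	Other	novel	novel	23.3	0.148	VUS	0.1
ST	1787123	SJST032198	PTC	RPA1	B	c.A1259T	p.Q420L	missense	NFE	0.0019%	0.0042%	22	0.16	VUS	0.8
ST	1787140	SJEWS019204	Sarcoma (EWS)	RPA1	coding, non DBD	c.T1276G	p.S426A	missense	NFE	0.0021%	0.0049%	24.1	0.191	VUS	-0.9
ST	1787161	SJNBL017202	NBL	RPA1	coding, non DBD	c.G1297A	p.G433S	missense	AFR	0.0157%	0.0508%	23.5	0.218	VUS	0
ST	1787173	SJSTS042513	Sarcoma (synovial)	RPA1	C	c.G1309A	p.G437R	missense	AFR	0.0134%	0.1397%	24.4	0.286	VUS	unavailable
ST	1787173	SJSTS019626	WT	RPA1	C	c.G1309A	p.G437R	missense	AFR	0.0134%	0.1397%	24.4	0.286	VUS	0.4
ST	1792008	SJRB019561	RB	RPA1	C	c.C1414T	p.R472C	missense	AFR	0.0026%	0.0212%	35	0.542	VUS	-0.2
ST	1792111	SJNPC019502	NPC	RPA1	C	c.A1517T	p.E506V	missense	AFR	0.0034%	0.0381%	32	0.387	VUS	0.6
ST	1792120	SJRB017939	RB	RPA1	C	c.A1526G	p.N509S	missense	NFE	0.0008%	novel	20.6	0.141	VUS	0.2
ST	1795196	SJNBL018730	NBL	RPA1	C	c.G1621A	p.G541R	missense	NFE	novel	novel	26.1	0.591	VUS	0.6
ST	1795226	SJNBL017207	NBL	RPA1	C	c.A1651C	p.K551Q	missense	NFE	novel	novel	22.7	0.282	VUS	unavailable
ST	1800386	SJOS018814	Sarcoma (OS)	RPA1	C	c.A1768G	p.T590A	missense	AMR	0.0050%	0.0325%	23.1	0.15	VUS	-0.2
ST	1800407	SJNBL042729	NBL	RPA1	C	c.G1789A	p.V597M	missense	NFE	0.0011%	0.0014%	27.8	0.292	VUS	unavailable
CNS	1778987	SJLGG031132	LGG (Ganglioglioma)	RPA1	coding, non DBD	c.A487G	p.K163E	missense	NFE	0.0008%	0.0010%	16.67	0.128	VUS	unavailable
CNS	1782296	SJEPD030782	EPD	RPA1	A	c.C700G	p.R234G	missense	NFE	0.0008%	0.0019%	28	0.598	VUS	1.5
CNS	1782605	SJMB030776	MB	RPA1	A	c.G856T	p.V286F	missense	AMR	0.0097%	novel	33	0.373	VUS	-0.4
CNS	1782646	SJMB032506	MB	RPA1	coding, non DBD	c.G897C	p.Q299H	missense	NFE	novel	novel	22.4	0.081	VUS	-0.2
CNS	1787173	SJHGG117	HGG	RPA1	C	c.G1309A	p.G437R	missense	AFR	0.0134%	0.1397%	24.4	0.286	VUS	unavailable
CNS	1787173	SJHGG030703	HGG (HGNET)	RPA1	C	c.G1309A	p.G437R	missense	AFR	0.0134%	0.1397%	24.4	0.286	VUS	unavailable
CNS	1792075	SJHGG067	HGG	RPA1	C	c.A1481G	p.Q494R	missense	EAS	novel	novel	23.5	0.202	VUS	-0.1
CNS	1792089	SJLGG030365	LGG	RPA1	C	c.C1495T	p.R499C	missense	AMR	0.0052%	0.0171%	35	0.435	VUS	-0.1
CNS	1792113	SJCNS018575	MB	RPA1	C	c.T1519C	p.F507L	missense	NFE	novel	novel	28.7	0.179	VUS	0.6
CNS	1792132	SJLGG046	LGG	RPA1	C	c.G1538A	p.R513H	missense	NFE	0.0164%	0.0331%	35	0.535	VUS	0.4
CNS	1792139	SJHGG100	HGG	RPA1	C	c.C1545G	p.I515M	missense	NFE	0.0008%	novel	17.81	0.074	VUS	0.5
CNS	1800398	SJST032495	MB	RPA1	C	c.G1780A	p.V594M	missense	NFE	novel	novel	33	0.419	VUS	0.7
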