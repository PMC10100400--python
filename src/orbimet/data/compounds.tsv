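compound_id	name	formula
M0001	tryptophan	C11H12N2O2
M0002	N-formylkynurenine	C11H12N2O4
M0003	kynurenine	C10H12N2O3
M0004	kynurenic acid	C10H7NO3
M0005	anthranilate	C7H7NO2
M0006	3-hydroxykynurenine	C10H12N2O4
M0007	3-hydroxyanthranilate	C7H7NO3
M0008	xanthurenic acid	C10H7NO4
M0009	quinolinate	C7H5NO4
M0010	picolinate	C6H5NO2
M0011	2-aminomuconate semialdehyde	C6H7NO3
M0012	2-aminomuconate	C6H7NO4
M0013	kynuramine	C9H12N2O
M0014	serotonin	C10H12N2O
M0015	5-hydroxytryptophan	C11H12N2O3
M0016	5-hydroxyindoleacetate	C10H9NO3
M0017	tryptamine	C10H12N2
M0018	indole	C8H7N
M0019	indole-3-acetaldehyde	C10H9NO
M0020	indole-3-acetate	C10H9NO2
M0021	indole-3-pyruvate	C11H9NO3
M0022	indole-3-lactate	C11H11NO3
M0023	melatonin	C13H16N2O2
M0024	N-acetylserotonin	C12H14N2O2
M0025	4,6-dihydroxyquinoline	C9H7NO2
M0026	5-hydroxyindole	C8H7NO
M0027	N-formylanthranilate	C8H7NO3
M0028	3-methylindole	C9H9N
M0029	formyl-5-hydroxykynurenamine	C10H12N2O2
M0030	arginine	C6H14N4O2
M0031	ornithine	C5H12N2O2
M0032	citrulline	C6H13N3O3
M0033	proline	C5H9NO2
M0034	4-hydroxyproline	C5H9NO3
M0035	glutamate	C5H9NO4
M0036	glutamine	C5H10N2O3
M0037	creatine	C4H9N3O2
M0038	creatinine	C4H7N3O
M0039	putrescine	C4H12N2
M0040	spermidine	C7H19N3
M0041	spermine	C10H26N4
M0042	agmatine	C5H14N4
M0043	4-aminobutanoate	C4H9NO2
M0044	1-pyrroline-5-carboxylate	C5H7NO2
M0045	N-acetylornithine	C7H14N2O3
M0046	argininosuccinate	C10H18N4O6
M0047	guanidinoacetate	C3H7N3O2
M0048	urea	CH4N2O
M0049	N-acetylputrescine	C6H14N2O
M0050	tyrosine	C9H11NO3
M0051	levodopa	C9H11NO4
M0052	dopamine	C8H11NO2
M0053	norepinephrine	C8H11NO3
M0054	epinephrine	C9H13NO3
M0055	3-methoxytyramine	C9H13NO2
M0056	tyramine	C8H11NO
M0057	phenylethanolamine	C8H11NO
M0058	homovanillate	C9H10O4
M0059	4-hydroxyphenylpyruvate	C9H8O4
M0060	homogentisate	C8H8O4
M0061	4-hydroxyphenylacetate	C8H8O3
M0062	fumarylacetoacetate	C8H8O5
M0063	metanephrine	C10H15NO3
M0064	vanillylmandelate	C9H10O5
M0065	3,4-dihydroxyphenylacetate	C8H8O4
M0066	phenylalanine	C9H11NO2
M0067	4-hydroxyphenyllactate	C9H10O4
M0068	phenylpyruvate	C9H8O3
M0069	thyroxine	C15H11I4NO4
M0070	histidine	C6H9N3O2
M0071	histamine	C5H9N3
M0072	urocanate	C6H6N2O2
M0073	imidazole-4-acetate	C5H6N2O2
M0074	carnosine	C9H14N4O3
M0075	anserine	C10H16N4O3
M0076	1-methylhistidine	C7H11N3O2
M0077	3-methylhistidine	C7H11N3O2
M0078	N-formimino-L-glutamate	C6H10N2O5
M0079	methylimidazoleacetate	C6H8N2O2
M0080	imidazolone propionate	C6H8N2O3
M0081	hydantoin-5-propionate	C6H8N2O4
M0082	cytosine	C4H5N3O
M0083	phosphoric acid	H3PO4
M0084	purine	C5H4N4
M0085	xanthine	C5H4N4O2
M0086	8-hydroxy-7-methylguanine	C6H7N5O2
M0087	adenine	C5H5N5
M0088	guanine	C5H5N5O
M0089	hypoxanthine	C5H4N4O
M0090	uric acid	C5H4N4O3
M0091	uracil	C4H4N2O2
M0092	thymine	C5H6N2O2
M0093	cytidine	C9H13N3O5
M0094	adenosine	C10H13N5O4
M0095	guanosine	C10H13N5O5
M0096	inosine	C10H12N4O5
M0097	xanthosine	C10H12N4O6
M0098	uridine	C9H12N2O6
M0099	thymidine	C10H14N2O5
M0100	deoxycytidine	C9H13N3O4
M0101	orotate	C5H4N2O4
M0102	dihydroorotate	C5H6N2O4
M0103	allantoin	C4H6N4O3
M0104	5-methylcytosine	C5H7N3O
M0105	7-methylguanine	C6H7N5O
M0106	1-methyladenine	C6H7N5
M0107	1-methyluric acid	C6H6N4O3
M0108	AMP	C10H14N5O7P
M0109	GMP	C10H14N5O8P
M0110	UMP	C9H13N2O9P
M0111	CMP	C9H14N3O8P
M0112	ADP	C10H15N5O10P2
M0113	ATP	C10H16N5O13P3
M0114	glycine	C2H5NO2
M0115	alanine	C3H7NO2
M0116	serine	C3H7NO3
M0117	threonine	C4H9NO3
M0118	valine	C5H11NO2
M0119	leucine	C6H13NO2
M0120	methionine	C5H11NO2S
M0121	cysteine	C3H7NO2S
M0122	cystine	C6H12N2O4S2
M0123	lysine	C6H14N2O2
M0124	aspartate	C4H7NO4
M0125	asparagine	C4H8N2O3
M0126	taurine	C2H7NO3S
M0127	homocysteine	C4H9NO2S
M0128	cystathionine	C7H14N2O4S
M0129	methionine sulfoxide	C5H11NO3S
M0130	N-acetylaspartate	C6H9NO5
M0131	S-adenosylhomocysteine	C14H20N6O5S
M0132	citrate	C6H8O7
M0133	cis-aconitate	C6H6O6
M0134	alpha-ketoglutarate	C5H6O5
M0135	succinate	C4H6O4
M0136	fumarate	C4H4O4
M0137	malate	C4H6O5
M0138	oxaloacetate	C4H4O5
M0139	pyruvate	C3H4O3
M0140	lactate	C3H6O3
M0141	2-hydroxyglutarate	C5H8O5
M0142	3-hydroxybutyrate	C4H8O3
M0143	acetoacetate	C4H6O3
M0144	malonate	C3H4O4
M0145	adipate	C6H10O4
M0146	pimelate	C7H12O4
M0147	suberate	C8H14O4
M0148	azelate	C9H16O4
M0149	sebacate	C10H18O4
M0150	benzoate	C7H6O2
M0151	salicylate	C7H6O3
M0152	gentisate	C7H6O4
M0153	phenylacetate	C8H8O2
M0154	phenyllactate	C9H10O3
M0155	shikimate	C7H10O5
M0156	quinate	C7H12O6
M0157	gluconate	C6H12O7
M0158	glucuronate	C6H10O7
M0159	threonate	C4H8O5
M0160	hippurate	C9H9NO3
M0161	indoxyl sulfate	C8H7NO4S
M0162	p-cresol sulfate	C7H8O4S
M0163	glucose	C6H12O6
M0164	ribose	C5H10O5
M0165	sucrose	C12H22O11
M0166	raffinose	C18H32O16
M0167	stachyose	C24H42O21
M0168	glucose-6-phosphate	C6H13O9P
M0169	fructose-1,6-bisphosphate	C6H14O12P2
M0170	glycerol	C3H8O3
M0171	glycerol-3-phosphate	C3H9O6P
M0172	erythritol	C4H10O4
M0173	xylitol	C5H12O5
M0174	sorbitol	C6H14O6
M0175	N-acetylglucosamine	C8H15NO6
M0176	N-acetylneuraminate	C11H19NO9
M0177	UDP-glucose	C15H24N2O17P2
M0178	UDP-N-acetylglucosamine	C17H27N3O17P2
M0179	glutathione	C10H17N3O6S
M0180	glutathione disulfide	C20H32N6O12S2
M0181	NAD	C21H27N7O14P2
M0182	NADP	C21H28N7O17P3
M0183	FAD	C27H33N9O15P2
M0184	pantothenate	C9H17NO5
M0185	biotin	C10H16N2O3S
M0186	riboflavin	C17H20N4O6
M0187	pyridoxine	C8H11NO3
M0188	pyridoxal	C8H9NO3
M0189	folate	C19H19N7O6
M0190	ascorbate	C6H8O6
M0191	nicotinamide	C6H6N2O
M0192	ethanolamine	C2H7NO
M0193	phosphoethanolamine	C2H8NO4P
M0194	glycerophosphocholine	C8H20NO6P
M0195	carnitine	C7H15NO3
M0196	acetylcarnitine	C9H17NO4
M0197	palmitoylcarnitine	C23H45NO4
M0198	sphingosine	C18H37NO2
M0199	octanoate	C8H16O2
M0200	decanoate	C10H20O2
M0201	laurate	C12H24O2
M0202	myristate	C14H28O2
M0203	palmitate	C16H32O2
M0204	palmitoleate	C16H30O2
M0205	stearate	C18H36O2
M0206	oleate	C18H34O2
M0207	linoleate	C18H32O2
M0208	alpha-linolenate	C18H30O2
M0209	arachidonate	C20H32O2
M0210	eicosapentaenoate	C20H30O2
M0211	docosahexaenoate	C22H32O2
M0212	arachidate	C20H40O2
M0213	behenate	C22H44O2
M0214	lignocerate	C24H48O2
M0215	cholesterol	C27H46O
M0216	cholate	C24H40O5
M0217	chenodeoxycholate	C24H40O4
M0218	taurocholate	C26H45NO7S
M0219	glycocholate	C26H43NO6
M0220	LPA 16:0	C19H39O7P
M0221	LPE 16:0	C21H44NO7P
M0222	LPE 18:1	C23H46NO7P
M0223	PE 34:1	C39H76NO8P
M0224	PG 34:1	C40H77O10P
M0225	PI 38:4	C47H83O13P
M0226	PS 36:1	C42H80NO10P
M0227	ceramide d18:1/16:0	C34H67NO3
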