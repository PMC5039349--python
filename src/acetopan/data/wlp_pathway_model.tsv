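step_id	pathway	enzyme	gene_symbol	reference_protein	figure	reported_strains	notes
wlp1_fdhF	WLP core group I	formate dehydrogenase (selenocysteine-containing)	fdhF	REF_fdhF	F4	14	copy number varies; three copies in C. ljungdahlii and C. autoethanogenum
wlp1_fdhD	WLP core group I	formate dehydrogenase accessory protein	fdhD	REF_fdhD	F4	14	single gene cluster with fdhF in C. difficile
wlp2_fhs	WLP core group II	formyl-THF synthase	fhs	REF_fhs	F4	14	methyl branch entry; invests one ATP
wlp2_fchA	WLP core group II	formyl-THF cyclohydrolase	fchA	REF_fchA	F4	13	absent only in M. thermoacetica; MDH substitutes for the cyclization
wlp2_folD	WLP core group II	methylene-THF dehydrogenase	folD	REF_folD	F4	14
wlp2_metF	WLP core group II	methylene-THF reductase subunit	metF	REF_metF	F4	13	absent in Tr. primitia
wlp2_metV	WLP core group II	methylene-THF reductase subunit	metV	REF_metV	F4	12	absent in Ac. arabaticum and Tr. primitia
wlp2_acsE	WLP core group II	methyltransferase	acsE	REF_acsE	F4	14	duplicated in A. woodii and E. limosum
wlp2_acsC	WLP core group II	corrinoid Fe-S protein large subunit	acsC	REF_acsC	F4	14
wlp2_acsD	WLP core group II	corrinoid Fe-S protein small subunit	acsD	REF_acsD	F4	14
wlp2_acsA	WLP core group II	CO dehydrogenase	acsA	REF_acsA	F4	14	carbonyl branch
wlp2_acsF	WLP core group II	CODH accessory protein	acsF	REF_acsF	F4	14	acsB/C/D/E/F always one gene cluster
wlp2_cooC	WLP core group II	CODH maturation factor	cooC	REF_cooC	F4	14
wlp2_acsB	WLP core group II	acetyl-CoA synthase	acsB	REF_acsB	F4	14
wlp2_lpdA	WLP core group II	dihydrolipoamide dehydrogenase	lpdA	REF_lpdA	F4	14	two copies in C. difficile
wlp2_gcvH	WLP core group II	glycine-cleavage system H protein	gcvH	REF_gcvH	F4		dispensable; complete glycine cleavage system only in non-acetogen C. sticklandii
wlp3_pta	WLP core group III	phosphotransacetylase	pta	REF_pta	F4	10	unidentified in C. difficile, C. aceticum, E. limosum, M. thermoacetica; ptb/buk or pduL proposed alternatives
wlp3_ack	WLP core group III	acetate kinase	ack	REF_ack	F4	14	single copy except two in Ac. arabaticum
ccm_adhE	central carbon	bifunctional aldehyde/alcohol dehydrogenase	adhE	REF_adhE	F5	14
ccm_aor	central carbon	aldehyde:ferredoxin oxidoreductase	aor	REF_aor	F5		dispensable
ccm_fabK	central carbon	enoyl-ACP reductase	fabK	REF_fabK	F5	13	absent in Tr. primitia
ccm_frd	central carbon	fumarate reductase	frdA	REF_frdA	F5	8	reductive TCA branch
ccm_gltA	central carbon	citrate synthase	gltA	REF_gltA	F5	7	oxidative TCA branch
ccm_icd	central carbon	isocitrate dehydrogenase	icd	REF_icd	F5	10	absent in Tr. primitia, Th. kivui, C. ljungdahlii, C. autoethanogenum
ccm_kor	central carbon	2-oxoglutarate synthase	korA	REF_korA	F5	10	absent in Tr. primitia, Th. kivui, C. ljungdahlii, C. autoethanogenum
ccm_pfor	central carbon	pyruvate:ferredoxin oxidoreductase	pfor	REF_pfor	F5	12	not identified in Ca. hydrogenoformans and T. phaeum; pyruvate formate lyase alternative
ccm_ilvB	central carbon	acetolactate synthase	ilvB	REF_ilvB	F5	14	branched-chain amino acid entry
ccm_ilvC	central carbon	ketol-acid reductoisomerase	ilvC	REF_ilvC	F5	14
ccm_ilvD	central carbon	dihydroxy-acid dehydratase	ilvD	REF_ilvD	F5	14
ccm_aroD	central carbon	3-dehydroquinate dehydratase	aroD	REF_aroD	F5	13	absent in Tr. primitia
cof_folA	THF biosynthesis	dihydrofolate reductase	folA	REF_folA	F6		missing in most acetogens; oxygen-insensitive nitroreductase proposed alternative
cof_moaA	molybdopterin biosynthesis	GTP 3',8-cyclase	moaA	REF_moaA	F6	14	precursor Z synthesis
cof_moaC	molybdopterin biosynthesis	cyclic pyranopterin monophosphate synthase	moaC	REF_moaC	F6	14
cof_moaD	molybdopterin biosynthesis	molybdopterin synthase sulfur carrier	moaD	REF_moaD	F6	14
cof_moeB	molybdopterin biosynthesis	molybdopterin-synthase adenylyltransferase	moeB	REF_moeB	F6	14
cof_moaE	molybdopterin biosynthesis	molybdopterin synthase catalytic subunit	moaE	REF_moaE	F6	0	not reported in any acetogen; cysteine desulfurase proposed alternative
cof_fwdE	formylmethanofuran dehydrogenase	tungsten formylmethanofuran dehydrogenase subunit E	fwdE	REF_fwdE	F4	14	fwdABCD absent in all 14 genomes
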