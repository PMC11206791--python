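gene_id	name	source_species	locus_id	function_class	fl_clade	substrate_tags
gltA	gltA	B. longum	lnp	SBP	none	LNB;GNB;LNT
gltB	gltB	B. longum	lnp	permease	none	LNB
gltC	gltC	B. longum	lnp	permease	none	LNB
lnpA	lnpA	B. longum	lnp	GH112	none	LNB;GNB
nahK	nahK	B. longum	lnp	catabolic	none	GlcNAc
galT	galT	B. longum	lnp	catabolic	none	galactose
galE	galE	B. longum	lnp	catabolic	none	galactose
gltA_adult	gltA-BLLJ	B. longum		SBP	none	LNB;GNB
gltB_adult	gltB-BLLJ	B. longum		permease	none	LNB
gltC_adult	gltC-BLLJ	B. longum		permease	none	LNB
gltA_infant	gltA-BLNG	B. longum		SBP	none	LNB;GNB;LNT
gltB_infant	gltB-BLNG	B. longum		permease	none	LNB
gltC_infant	gltC-BLNG	B. longum		permease	none	LNB
nahS	nahS	B. breve	nah	SBP	none	LNT;LNnT
nahT1	nahT1	B. breve	nah	permease	none	LNT;LNnT
nahT2	nahT2	B. breve	nah	permease	none	LNT;LNnT
nahA	nahA	B. breve	nah	GH42	none	LNT;LNnT;lactose;dual_activity
nahB	nahB	B. breve	nah	GH20	none	LNT;LNnT
nahR	nahR	B. breve	nah	regulator	none	
lntS	lntS	B. breve	lnt	SBP	none	LNT
lntP1	lntP1	B. breve	lnt	permease	none	LNT
lntP2	lntP2	B. breve	lnt	permease	none	LNT
lntA	lntA	B. breve	lnt	GH42	none	LNT;LNnT;lactose;dual_activity
lntR	lntR	B. breve	lnt	regulator	none	
nagA	nagA	B. infantis	nag	catabolic	none	GlcNAc
nagB	nagB	B. infantis	nag	catabolic	none	GlcNAc
nagK	nagK	B. infantis	nag	catabolic	none	GlcNAc
gltF	gltF	B. infantis	nag	SBP	none	GNB
gltG	gltG	B. infantis	nag	permease	none	GNB
gltH	gltH	B. infantis	nag	ATP_binding	none	GNB
hmoS1	Blon_2344	B. infantis	H1	SBP	none	LNnT
hmoS2	Blon_2347	B. infantis	H1	SBP	none	LNT;LNnT
hmoS3	Blon_2351	B. infantis	H1	SBP	none	GNB
gh20_H1	Blon_2355	B. infantis	H1	GH20	none	LNT;LNnT
gh29_H1	Blon_2336	B. infantis	H1	GH29	none	FL3
gh95_H1	Blon_2335	B. infantis	H1	GH95	none	FL2p
gh33_H1	NanH2	B. infantis	H1	GH33	none	SL3p;SL6p
bga2A	Bga2A	B. infantis	H1	GH2	none	LNnT;lactose
fucT1	fucT1	B. infantis	H2	SBP	none	fucose
fucT2	fucT2	B. infantis	H2	permease	none	fucose
fucT3	fucT3	B. infantis	H2	permease	none	fucose
fl2_II_sbp	Blon_2202	B. infantis	FL_cluster_1	SBP	FL2_II	FL2p;FL3
fl1_perm1	Blon_2203a	B. infantis	FL_cluster_1	permease	none	FL2p;FL3
fl1_perm2	Blon_2203b	B. infantis	FL_cluster_1	permease	none	FL2p;FL3
fucI	fucI	B. infantis	FL_cluster_2	catabolic	none	fucose
fucK	fucK	B. infantis	FL_cluster_2	catabolic	none	fucose
fucD	fucD	B. infantis	FL_cluster_2	catabolic	none	fucose
fl1_IV_sbp	Blon_0343	B. infantis	FL_cluster_3	SBP	FL1_IV	FL2p;FL3
fl3_perm1	Blon_0344	B. infantis	FL_cluster_3	permease	none	FL2p;FL3
fl3_perm2	Blon_0345	B. infantis	FL_cluster_3	permease	none	FL2p;FL3
gh151_fl3	Blon_0346	B. infantis	FL_cluster_3	GH151	none	FL2p
fl2_III_sbp	FL2-III-BP	B. kashiwanohense	FHMO_cluster	SBP	FL2_III	FL2p;FL3
fhmo_perm1	fhmoP1	B. kashiwanohense	FHMO_cluster	permease	none	FL2p;FL3
fhmo_perm2	fhmoP2	B. kashiwanohense	FHMO_cluster	permease	none	FL2p;FL3
afcA_f	AfcA	B. kashiwanohense	FHMO_cluster	GH95	none	FL2p
afcB_f	AfcB	B. kashiwanohense	FHMO_cluster	GH29	none	FL3
fucU	FucU	B. kashiwanohense	FHMO_cluster	other	none	fucose
fhmo_fucD	fucD-f	B. kashiwanohense	FHMO_cluster	catabolic	none	fucose
fhmo_fucK	fucK-f	B. kashiwanohense	FHMO_cluster	catabolic	none	fucose
fhmoR	fhmoR	B. kashiwanohense	FHMO_cluster	regulator	none	
gltA_pc	gltA-PC	B. pseudocatenulatum	LNB_LNT_cluster	SBP	none	LNB;LNT
gltB_pc	gltB-PC	B. pseudocatenulatum	LNB_LNT_cluster	permease	none	LNB;LNT
gltC_pc	gltC-PC	B. pseudocatenulatum	LNB_LNT_cluster	permease	none	LNB;LNT
nagA_pc	nagA-PC	B. pseudocatenulatum	LNB_LNT_cluster	catabolic	none	GlcNAc
nagB_pc	nagB-PC	B. pseudocatenulatum	LNB_LNT_cluster	catabolic	none	GlcNAc
gh20_pc	BBPC_1688	B. pseudocatenulatum	LNB_LNT_cluster	GH20	none	LNT
lnbX	lnbX	B. longum	lnbXY	GH136	none	LNT
lnbY	lnbY	B. longum	lnbXY	chaperone	none	LNT
afcA_bb	AfcA	B. bifidum	bbext	GH95	none	FL2p
afcB_bb	AfcB	B. bifidum	bbext	GH29	none	FL3
siaBb2	SiaBb2	B. bifidum	bbext	GH33	none	SL3p;SL6p
bbgIII	BbgIII	B. bifidum	bbext	GH2	none	LNT;LNnT;lactose
bbhI	BbhI	B. bifidum	bbext	GH20	none	LNT;LNnT
lnbB	LnbB	B. bifidum	bbext	GH20	none	LNT
lnpA1	LnpA1	B. bifidum	bbext	GH112	none	LNB;GNB
hmoA2	hmoA2	B. scardovii	hmo2	SBP	none	LNT;LNnT
hmoB2	hmoB2	B. scardovii	hmo2	permease	none	LNT;LNnT
hmoC2	hmoC2	B. scardovii	hmo2	permease	none	LNT;LNnT
gnbS	BLNG_0933	B. longum	gnb_t	SBP	none	GNB
gnbP1	BLNG_0934	B. longum	gnb_t	permease	none	GNB
gnbP2	BLNG_0935	B. longum	gnb_t	permease	none	GNB
gnbA	BLNG_0936	B. longum	gnb_t	ATP_binding	none	GNB
bga42A	Bga42A	B. infantis		GH42	none	LNT;LNnT;lactose;dual_activity
lacZ6	lacZ6	B. breve		GH2	none	lactose;LNnT
lacZ2	lacZ2	B. breve		GH2	none	lactose
gh20_core	Blon_0732	B. infantis		GH20	none	LNT;LNnT
gh20_aux	Blon_0459	B. infantis		GH20	none	LNT;LNnT
gh29_extra	AfcB-breve	B. breve		GH29	none	FL3
gh33_int	SiaBbr	B. breve		GH33	none	SL3p;SL6p
gh2_sc	GH2-sc	B. scardovii		GH2	none	LNnT
gh29_sc1	GH29-sc1	B. scardovii		GH29	none	FL3
gh29_sc2	GH29-sc2	B. scardovii		GH29	none	FL3
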