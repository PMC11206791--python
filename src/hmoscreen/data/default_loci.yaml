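# Default locus definitions for the shipped HMO-utilization catalog.
#
# Schema:
#   loci:
#     <locus_id>:
#       members: [gene_id, ...]            # ordered roster
#       required_for_complete: [...]       # default: all members
#       required_for_functional: [...]     # default: all members
#       variant_refs: {label: [gene_id, ...]}   # optional
#   species_expectations:
#     <species>: [locus_id or gene_id, ...]
loci:
  lnp:
    members: [gltA, gltB, gltC, lnpA, nahK, galT, galE]
    required_for_functional: [gltA, gltB, gltC, lnpA]
    variant_refs:
      adult: [gltA_adult, gltB_adult, gltC_adult]
      infant: [gltA_infant, gltB_infant, gltC_infant]
  nah:
    members: [nahS, nahT1, nahT2, nahA, nahB, nahR]
    required_for_functional: [nahS, nahT1, nahT2]
  lnt:
    members: [lntS, lntP1, lntP2, lntA, lntR]
    required_for_functional: [lntS, lntP1, lntP2]
  nag:
    members: [nagA, nagB, nagK, gltF, gltG, gltH]
    required_for_functional: [nagA, nagB, nagK]
  H1:
    members: [hmoS1, hmoS2, hmoS3, gh20_H1, gh29_H1, gh95_H1, gh33_H1, bga2A]
  H2:
    members: [fucT1, fucT2, fucT3]
  FL_cluster_1:
    members: [fl2_II_sbp, fl1_perm1, fl1_perm2]
  FL_cluster_2:
    members: [fucI, fucK, fucD]
  FL_cluster_3:
    members: [fl1_IV_sbp, fl3_perm1, fl3_perm2, gh151_fl3]
    required_for_functional: [fl1_IV_sbp, fl3_perm1, fl3_perm2]
  FHMO_cluster:
    members: [fl2_III_sbp, fhmo_perm1, fhmo_perm2, afcA_f, afcB_f, fucU,
              fhmo_fucD, fhmo_fucK, fhmoR]
    required_for_functional: [fl2_III_sbp, fhmo_perm1, fhmo_perm2, afcA_f,
                              fhmo_fucD]
  LNB_LNT_cluster:
    members: [gltA_pc, gltB_pc, gltC_pc, nagA_pc, nagB_pc, gh20_pc]
    required_for_functional: [gltA_pc, gltB_pc, gltC_pc, gh20_pc]
  lnbXY:
    members: [lnbX, lnbY]
  bbext:
    members: [afcA_bb, afcB_bb, siaBb2, bbgIII, bbhI, lnbB, lnpA1]
  hmo2:
    members: [hmoA2, hmoB2, hmoC2]
  gnb_t:
    members: [gnbS, gnbP1, gnbP2, gnbA]

species_expectations:
  "B. breve": [lnt, nah, lnp, nag]
  "B. infantis": [H1, lnp, nag, FL_cluster_1, FL_cluster_2]
  "B. longum": [lnp, nag, bga42A, gh20_core]
  "B. bifidum": [bbext, lnp]
  "B. pseudocatenulatum": [LNB_LNT_cluster, bga42A, bga2A]
  "B. catenulatum": [bga42A, bga2A]
  "B. adolescentis": [gnb_t]
  "B. scardovii": [hmo2, gnb_t, bga42A]
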