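# Nitrogen-cycle marker groups.
#
# Each group lists the subunit genes recorded for it and the subset that must
# all be present for the group flag to be set (catalytic core by default;
# accessory subunits such as amoD/amoE or narI/narJ are recorded but not
# required). Phylogenetic qualifiers that cannot be read off a gene symbol
# (nosZ clade, nxr phyletic group) are carried as distinct symbols in the
# annotation table, assigned upstream from gene trees.
groups:
  amoCABDE:
    genes: [amoA, amoB, amoC, amoD, amoE]
    required: [amoA, amoB, amoC]
  hao:
    genes: [haoA, haoB]
    required: [haoA]
  hzsABC:
    genes: [hzsA, hzsB, hzsC]
    required: [hzsA, hzsB, hzsC]
  hdh:
    genes: [hdh]
    required: [hdh]
  nxrAB_anammox:
    genes: [nxrA_anammox, nxrB_anammox]
    required: [nxrA_anammox, nxrB_anammox]
  nxr_like_periplasmic:
    genes: [nxrA_periplasmic]
    required: [nxrA_periplasmic]
  nxr_canonical:
    genes: [nxrA_canonical, nxrB_canonical]
    required: [nxrA_canonical]
  narGHIJ:
    genes: [narG, narH, narI, narJ]
    required: [narG, narH]
  napAB:
    genes: [napA, napB]
    required: [napA]
  nirS:
    genes: [nirS]
    required: [nirS]
  nirK:
    genes: [nirK]
    required: [nirK]
  nirBD:
    genes: [nirB, nirD]
    required: [nirB]
  nrfHA:
    genes: [nrfH, nrfA]
    required: [nrfA]
  norBC:
    genes: [norB, norC]
    required: [norB, norC]
  norZ:
    genes: [norZ]
    required: [norZ]
  nosZ_cladeI:
    genes: [nosZ_cladeI]
    required: [nosZ_cladeI]
  nosZ_cladeII:
    genes: [nosZ_cladeII]
    required: [nosZ_cladeII]

# hao-like paralogs are deduplicated per copy in annotation tables
# (haoA_like_01, haoA_like_02, ...); the census counts symbols with this
# prefix. Their hypothesized activities enter only as optional network edges.
hao_like_prefix: haoA_like

# KO-number aliases accepted in annotation tables. nosZ and nxr KOs are
# deliberately absent: KEGG orthology does not resolve nosZ clades or nxr
# phyletic groups, which must arrive pre-labelled.
aliases:
  K10944: amoA
  K10945: amoB
  K10946: amoC
  K10535: haoA
  K20932: hzsA
  K20933: hzsB
  K20934: hzsC
  K20935: hdh
  K00370: narG
  K00371: narH
  K00374: narI
  K00373: narJ
  K02567: napA
  K02568: napB
  K15864: nirS
  K00368: nirK
  K00362: nirB
  K00363: nirD
  K03385: nrfA
  K15876: nrfH
  K04561: norB
  K02305: norC
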