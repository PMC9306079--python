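# Biosynthesis and carbon-fixation pathway definitions.
#
# Each step is a list of alternative enzymes (gene symbols and/or KO ids);
# any one of them satisfies the step. Amino-acid pathways are defined from
# their committed branch point (shared central-metabolism precursors are out
# of scope), which keeps each pathway's diagnostic genes distinct. Step lists
# are a reconstruction modelled on KEGG module structure, intended to be
# edited for other annotation vocabularies.
#
# Pathway-presence rule (see pathway_engine.call_pathway): pathways with more
# than two steps tolerate one missing step; pathways of one or two steps
# require every step.
pathways:
  # --- amino acids -------------------------------------------------------
  - id: aa_ala
    category: amino_acid
    name: alanine
    steps:
      - [alaA, alaC, avtA]
  - id: aa_arg
    category: amino_acid
    name: arginine
    steps:
      - [argA]
      - [argB]
      - [argC]
      - [argD]
      - [argE, argJ]
      - [argF]
      - [argG]
      - [argH]
  - id: aa_asn
    category: amino_acid
    name: asparagine
    steps:
      - [asnA, asnB]
  - id: aa_asp
    category: amino_acid
    name: aspartate
    steps:
      - [aspC]
  - id: aa_cys
    category: amino_acid
    name: cysteine
    steps:
      - [cysE]
      - [cysK, cysM]
  - id: aa_glu
    category: amino_acid
    name: glutamate
    steps:
      - [gdhA, gltB]
  - id: aa_gln
    category: amino_acid
    name: glutamine
    steps:
      - [glnA]
  - id: aa_gly
    category: amino_acid
    name: glycine
    steps:
      - [glyA]
  - id: aa_his
    category: amino_acid
    name: histidine
    steps:
      - [hisG]
      - [hisE]
      - [hisI]
      - [hisA]
      - [hisH]
      - [hisF]
      - [hisB]
      - [hisC]
      - [hisD]
  - id: aa_ile
    category: amino_acid
    name: isoleucine
    steps:
      - [ilvA]
      - [ilvB, ilvG, ilvI]
      - [ilvC]
      - [ilvD]
      - [ilvE]
  - id: aa_leu
    category: amino_acid
    name: leucine
    steps:
      - [leuA]
      - [leuC]
      - [leuD]
      - [leuB]
  - id: aa_lys
    category: amino_acid
    name: lysine
    steps:
      - [dapA]
      - [dapB]
      - [dapD, ddh]
      - [dapE]
      - [dapF]
      - [lysA]
  - id: aa_met
    category: amino_acid
    name: methionine
    steps:
      - [metA, metX]
      - [metB]
      - [metC, aecD]
      - [metE, metH]
  - id: aa_phe
    category: amino_acid
    name: phenylalanine
    steps:
      - [pheA]
      - [tyrB, aspC]
  - id: aa_pro
    category: amino_acid
    name: proline
    steps:
      - [proB]
      - [proA]
      - [proC]
  - id: aa_ser
    category: amino_acid
    name: serine
    steps:
      - [serA]
      - [serC]
      - [serB]
  - id: aa_thr
    category: amino_acid
    name: threonine
    steps:
      - [thrA, metL, lysC]
      - [asd]
      - [thrB]
      - [thrC]
  - id: aa_trp
    category: amino_acid
    name: tryptophan
    steps:
      - [trpE]
      - [trpD]
      - [trpC]
      - [trpA]
      - [trpB]
  - id: aa_tyr
    category: amino_acid
    name: tyrosine
    steps:
      - [tyrA]
      - [tyrB, aspC]
  - id: aa_val
    category: amino_acid
    name: valine
    steps:
      - [ilvB, ilvG, ilvI]
      - [ilvC]
      - [ilvD]
      - [ilvE]

  # --- B vitamins --------------------------------------------------------
  - id: vit_b1
    category: b_vitamin
    name: thiamine
    steps:
      - [thiC]
      - [thiD]
      - [thiG]
      - [thiE]
  - id: vit_b2
    category: b_vitamin
    name: riboflavin
    steps:
      - [ribA]
      - [ribD]
      - [ribH]
      - [ribE, ribC]
  - id: vit_b3
    category: b_vitamin
    name: niacin
    steps:
      - [nadB]
      - [nadA]
      - [nadC]
  - id: vit_b5
    category: b_vitamin
    name: pantothenate
    steps:
      - [panB]
      - [panE, apbA]
      - [panD]
      - [panC]
  - id: vit_b6
    category: b_vitamin
    name: pyridoxine
    steps:
      - [pdxA]
      - [pdxJ]
      - [pdxH]
  - id: vit_b7
    category: b_vitamin
    name: biotin
    steps:
      - [bioF]
      - [bioA]
      - [bioD]
      - [bioB]
  - id: vit_b9
    category: b_vitamin
    name: folate
    steps:
      - [folE]
      - [folB]
      - [folK]
      - [folP]
      - [folC]
      - [folA]
  - id: vit_b12
    category: b_vitamin
    name: cobalamin
    steps:
      - [cbiK, cobN]
      - [cbiL]
      - [cbiH]
      - [cbiF]
      - [cbiT]
      - [cobD]
      - [cobU]
      - [cobS]

  # --- carbon fixation ---------------------------------------------------
  # Autotrophy screening uses key_genes only (all required), not the
  # one-missing-step rule.
  - id: cfix_cbb
    category: carbon_fixation
    name: Calvin-Benson-Bassham cycle
    steps:
      - [rbcL]
      - [rbcS]
      - [prkB]
    key_genes: [rbcL, prkB]
  - id: cfix_wl
    category: carbon_fixation
    name: Wood-Ljungdahl pathway
    steps:
      - [acsA, cooS]
      - [acsB]
      - [acsE]
      - [fhs]
    key_genes: [acsA, acsB]
  - id: cfix_rtca
    category: carbon_fixation
    name: reductive TCA cycle
    steps:
      - [aclA]
      - [aclB]
      - [korA]
    key_genes: [aclA, aclB]
  - id: cfix_3hp
    category: carbon_fixation
    name: 3-hydroxypropionate cycle
    steps:
      - [mcr]
      - [pcs]
    key_genes: [mcr, pcs]
  - id: cfix_3hp4hb
    category: carbon_fixation
    name: 3-hydroxypropionate/4-hydroxybutyrate cycle
    steps:
      - [mcr]
      - [abfD]
    key_genes: [abfD, mcr]
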