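# Nitrogen-transformation rule table: which censused marker groups license
# which substrate -> product conversions.
#
# Intermediates: NH3, NH2OH, NO2-, NO3-, NO, N2O, N2, NH4+, N2H4.
# Anammox nxrAB is emitted reversible: the oxidative direction (NO2- -> NO3-)
# is the community's only NO3- source, the reductive direction keeps the
# enzyme's nar homology on the map. Periplasmic nxr-like genes carry no edge
# unless the nxr_as_nar switch is on (their direction is unresolved).
# hao-like paralog activities (hydroxylamine -> NO; nitrite -> NO/NH2OH) are
# hypotheses and stay off unless enable_hao_like_edges is set.
rules:
  - group: amoCABDE
    substrate: NH3
    product: NH2OH
  - group: hao
    substrate: NH2OH
    product: NO2-
  - group: nxr_canonical
    substrate: NO2-
    product: NO3-
  - group: nxrAB_anammox
    substrate: NO2-
    product: NO3-
    reversible: true
  - group: nxr_like_periplasmic
    substrate: NO3-
    product: NO2-
    switch: nxr_as_nar
  - group: narGHIJ
    substrate: NO3-
    product: NO2-
  - group: napAB
    substrate: NO3-
    product: NO2-
  - group: nirS
    substrate: NO2-
    product: "NO"
  - group: nirK
    substrate: NO2-
    product: "NO"
  - group: nirBD
    substrate: NO2-
    product: NH4+
  - group: nrfHA
    substrate: NO2-
    product: NH4+
  - group: norBC
    substrate: "NO"
    product: N2O
  - group: norZ
    substrate: "NO"
    product: N2O
  - group: nosZ_cladeI
    substrate: N2O
    product: N2
  - group: nosZ_cladeII
    substrate: N2O
    product: N2
  - group: hzsABC
    substrate: ["NO", NH4+]
    product: N2H4
  - group: hdh
    substrate: N2H4
    product: N2
  - group: hao_like
    substrate: NH2OH
    product: "NO"
    switch: enable_hao_like_edges
  - group: hao_like
    substrate: NO2-
    product: "NO"
    switch: enable_hao_like_edges
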