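# Default GO-term / keyword map onto the five functional categories used to
# reason about likely cellular location of skeletal matrix proteins.
# Edit freely; every report records the SHA-256 of the map in force.
rules:
  # -- membrane processing: lipid / phosphate / glycan metabolism ------------
  - {match: go, pattern: "GO:0006629", category: membrane_processing}   # lipid metabolic process
  - {match: go, pattern: "GO:0008610", category: membrane_processing}   # lipid biosynthetic process
  - {match: go, pattern: "GO:0016042", category: membrane_processing}   # lipid catabolic process
  - {match: go, pattern: "GO:0006644", category: membrane_processing}   # phospholipid metabolic process
  - {match: go, pattern: "GO:0006796", category: membrane_processing}   # phosphate-containing compound metabolism
  - {match: go, pattern: "GO:0070085", category: membrane_processing}   # glycosylation
  - {match: keyword, pattern: "phospholipase|sphingomyelin", category: membrane_processing}

  # -- ECM / transmembrane ---------------------------------------------------
  - {match: go, pattern: "GO:0005576", category: ecm_tm_protein_modification}  # extracellular region
  - {match: go, pattern: "GO:0031012", category: ecm_tm_protein_modification}  # extracellular matrix
  - {match: go, pattern: "GO:0005201", category: ecm_tm_protein_modification}  # ECM structural constituent
  - {match: go, pattern: "GO:0016021", category: ecm_tm_protein_modification}  # integral component of membrane
  - {match: keyword, pattern: "collagen|laminin|extracellular matrix", category: ecm_tm_protein_modification}

  # -- metal binding ---------------------------------------------------------
  - {match: go, pattern: "GO:0005509", category: metal_binding}   # calcium ion binding
  - {match: go, pattern: "GO:0046872", category: metal_binding}   # metal ion binding
  - {match: go, pattern: "GO:0008270", category: metal_binding}   # zinc ion binding
  - {match: go, pattern: "GO:0005506", category: metal_binding}   # iron ion binding
  - {match: go, pattern: "GO:0005507", category: metal_binding}   # copper ion binding

  # -- vesicular / secretion -------------------------------------------------
  - {match: go, pattern: "GO:0016192", category: vesicular_secretion}  # vesicle-mediated transport
  - {match: go, pattern: "GO:0006887", category: vesicular_secretion}  # exocytosis
  - {match: go, pattern: "GO:0031982", category: vesicular_secretion}  # vesicle
  - {match: go, pattern: "GO:0030133", category: vesicular_secretion}  # transport vesicle
  - {match: go, pattern: "GO:0046903", category: vesicular_secretion}  # secretion
  - {match: keyword, pattern: "exosome|synapsin|vesicle", category: vesicular_secretion}

  # -- protein modification --------------------------------------------------
  - {match: go, pattern: "GO:0036211", category: protein_modification}  # protein modification process
  - {match: go, pattern: "GO:0008233", category: protein_modification}  # peptidase activity
  - {match: go, pattern: "GO:0004672", category: protein_modification}  # protein kinase activity
  - {match: go, pattern: "GO:0016301", category: protein_modification}  # kinase activity
  - {match: go, pattern: "GO:0006486", category: protein_modification}  # protein glycosylation
  - {match: keyword, pattern: "peptidase|protease|proteinase|kinase", category: protein_modification}
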