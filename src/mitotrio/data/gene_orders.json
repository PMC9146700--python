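{
  "_comment": "Circular gene orders starting at the control region. Strand: light/heavy. 'ancestral_insect' is the proposed ancestral insect arrangement (Drosophila-like); 'apis_mellifera' is the honeybee arrangement. tRNA-Leu1 denotes the copy between cox1 and cox2, tRNA-Leu2 the copy adjacent to nd1; tRNA-Ser1 the AGN copy, tRNA-Ser2 the UCN copy after cytb.",
  "ancestral_insect": [
    ["control_region", "light"],
    ["tRNA-Ile", "light"],
    ["tRNA-Gln", "heavy"],
    ["tRNA-Met", "light"],
    ["nd2", "light"],
    ["tRNA-Trp", "light"],
    ["tRNA-Cys", "heavy"],
    ["tRNA-Tyr", "heavy"],
    ["cox1", "light"],
    ["tRNA-Leu1", "light"],
    ["cox2", "light"],
    ["tRNA-Lys", "light"],
    ["tRNA-Asp", "light"],
    ["atp8", "light"],
    ["atp6", "light"],
    ["cox3", "light"],
    ["tRNA-Gly", "light"],
    ["nd3", "light"],
    ["tRNA-Ala", "light"],
    ["tRNA-Arg", "light"],
    ["tRNA-Asn", "light"],
    ["tRNA-Ser1", "light"],
    ["tRNA-Glu", "light"],
    ["tRNA-Phe", "heavy"],
    ["nd5", "heavy"],
    ["tRNA-His", "heavy"],
    ["nd4", "heavy"],
    ["nd4l", "heavy"],
    ["tRNA-Thr", "light"],
    ["tRNA-Pro", "heavy"],
    ["nd6", "light"],
    ["cytb", "light"],
    ["tRNA-Ser2", "light"],
    ["nd1", "heavy"],
    ["tRNA-Leu2", "heavy"],
    ["16S rRNA", "heavy"],
    ["tRNA-Val", "heavy"],
    ["12S rRNA", "heavy"]
  ],
  "apis_mellifera": [
    ["control_region", "light"],
    ["tRNA-Glu", "light"],
    ["tRNA-Ser1", "light"],
    ["tRNA-Met", "light"],
    ["tRNA-Gln", "light"],
    ["tRNA-Ala", "light"],
    ["tRNA-Ile", "light"],
    ["nd2", "light"],
    ["tRNA-Cys", "heavy"],
    ["tRNA-Tyr", "heavy"],
    ["tRNA-Trp", "light"],
    ["cox1", "light"],
    ["tRNA-Leu1", "light"],
    ["cox2", "light"],
    ["tRNA-Asp", "light"],
    ["tRNA-Lys", "light"],
    ["atp8", "light"],
    ["atp6", "light"],
    ["cox3", "light"],
    ["tRNA-Gly", "light"],
    ["nd3", "light"],
    ["tRNA-Arg", "heavy"],
    ["tRNA-Asn", "light"],
    ["tRNA-Phe", "heavy"],
    ["nd5", "heavy"],
    ["tRNA-His", "heavy"],
    ["nd4", "heavy"],
    ["nd4l", "heavy"],
    ["tRNA-Thr", "light"],
    ["tRNA-Pro", "heavy"],
    ["nd6", "light"],
    ["cytb", "light"],
    ["tRNA-Ser2", "light"],
    ["nd1", "heavy"],
    ["tRNA-Leu2", "heavy"],
    ["16S rRNA", "heavy"],
    ["tRNA-Val", "heavy"],
    ["12S rRNA", "heavy"]
  ]
}
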