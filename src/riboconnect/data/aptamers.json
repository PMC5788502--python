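{
  "note": "Synthetic aptamer library. Each entry is a SYNTHETIC stem-loop reconstruction of the device architecture (7 bp stem, AAAA loop) standing in for the experimentally selected aptamer of the named ligand; sequences are NOT the published aptamer sequences. The stem interval is the 5' stem strand, the strand a sequestration switch hybridizes against. binding_bonus is the ligand-binding stabilization in fold-score units: 5.0 for small-molecule ligands, 7.0 for protein ligands.",
  "entries": [
    {
      "id": "theo",
      "ligand": "theophylline",
      "sequence": "GGCGAUGAAAACAUCGCC",
      "reference_structure": "(((((((....)))))))",
      "stem": [
        0,
        7
      ],
      "role": "sensor",
      "binding_bonus": 5.0
    },
    {
      "id": "tet",
      "ligand": "tetracycline",
      "sequence": "GCAGGCCAAAAGGCCUGC",
      "reference_structure": "(((((((....)))))))",
      "stem": [
        0,
        7
      ],
      "role": "sensor",
      "binding_bonus": 5.0
    },
    {
      "id": "eif4g",
      "ligand": "eIF4G",
      "sequence": "GGAGGCGAAAACGCCUCC",
      "reference_structure": "(((((((....)))))))",
      "stem": [
        0,
        7
      ],
      "role": "effector",
      "binding_bonus": 7.0
    },
    {
      "id": "bcat",
      "ligand": "beta-catenin",
      "sequence": "GCGUGGCAAAAGCCACGC",
      "reference_structure": "(((((((....)))))))",
      "stem": [
        0,
        7
      ],
      "role": "sensor",
      "binding_bonus": 7.0
    },
    {
      "id": "nfkb",
      "ligand": "NF-kB",
      "sequence": "GGGCAUGAAAACAUGCCC",
      "reference_structure": "(((((((....)))))))",
      "stem": [
        0,
        7
      ],
      "role": "sensor",
      "binding_bonus": 7.0
    },
    {
      "id": "vegf",
      "ligand": "VEGF",
      "sequence": "GCCGAGCAAAAGCUCGGC",
      "reference_structure": "(((((((....)))))))",
      "stem": [
        0,
        7
      ],
      "role": "sensor",
      "binding_bonus": 7.0
    },
    {
      "id": "opn",
      "ligand": "OPN",
      "sequence": "GGUCGCGAAAACGCGACC",
      "reference_structure": "(((((((....)))))))",
      "stem": [
        0,
        7
      ],
      "role": "sensor",
      "binding_bonus": 7.0
    }
  ]
}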