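{
  "_comment": "Synthetic stand-in profiles for the eight cryo-EM tauopathy protofilament folds. modeled_ranges approximate each deposition's ordered core in 2N4R author numbering; planted_contacts encode the reported sidechain neighbourhoods of the PHF6/PHF6* suffix residues (VYK 309-311, INK 278-280). Stand-in structures built from these profiles are synthetic: residue placement is schematic, only the planted pair distances are meaningful.",
  "AD": {
    "pdb_id": "5O3L",
    "disease": "Alzheimer's disease",
    "modeled_ranges": [[306, 378]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 310, "atom_a": "CD1", "res_b": 376, "atom_b": "CD1", "distance": 4.2, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "OH", "res_b": 374, "atom_b": "NE2", "distance": 3.0, "type": "hbond"}
    ]
  },
  "CTE": {
    "pdb_id": "6NWP",
    "disease": "chronic traumatic encephalopathy",
    "modeled_ranges": [[305, 379]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 310, "atom_a": "CD1", "res_b": 376, "atom_b": "CD1", "distance": 4.4, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "OH", "res_b": 374, "atom_b": "NE2", "distance": 3.1, "type": "hbond"}
    ]
  },
  "PiD": {
    "pdb_id": "6GX5",
    "disease": "Pick's disease",
    "modeled_ranges": [[254, 274], [306, 378]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 310, "atom_a": "CE1", "res_b": 337, "atom_b": "CG1", "distance": 4.1, "type": "hydrophobic"}
    ]
  },
  "CBD": {
    "pdb_id": "6TJO",
    "disease": "corticobasal degeneration",
    "modeled_ranges": [[274, 380]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 309, "atom_a": "CG1", "res_b": 297, "atom_b": "CD1", "distance": 4.3, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "CE1", "res_b": 337, "atom_b": "CG1", "distance": 4.0, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 311, "atom_a": "CD", "res_b": 297, "atom_b": "CG2", "distance": 4.6, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 311, "atom_a": "NZ", "res_b": 295, "atom_b": "OD1", "distance": 2.9, "type": "hbond"},
      {"motif": "PHF6*", "res_a": 279, "atom_a": "ND2", "res_b": 376, "atom_b": "O", "distance": 3.0, "type": "hbond"}
    ]
  },
  "AGD": {
    "pdb_id": "7P6D",
    "disease": "argyrophilic grain disease",
    "modeled_ranges": [[273, 387]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 309, "atom_a": "CG1", "res_b": 297, "atom_b": "CD1", "distance": 4.2, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "CE1", "res_b": 337, "atom_b": "CG1", "distance": 4.3, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 311, "atom_a": "NZ", "res_b": 295, "atom_b": "OD1", "distance": 3.0, "type": "hbond"}
    ]
  },
  "PSP": {
    "pdb_id": "7P65",
    "disease": "progressive supranuclear palsy",
    "modeled_ranges": [[272, 381]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 309, "atom_a": "CG1", "res_b": 350, "atom_b": "CG1", "distance": 4.1, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 309, "atom_a": "CG2", "res_b": 348, "atom_b": "CB", "distance": 4.5, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "CD1", "res_b": 301, "atom_b": "CG", "distance": 4.4, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "OH", "res_b": 299, "atom_b": "NE2", "distance": 3.1, "type": "hbond"},
      {"motif": "PHF6", "res_a": 311, "atom_a": "NZ", "res_b": 348, "atom_b": "OD1", "distance": 2.9, "type": "hbond"}
    ]
  },
  "GGT": {
    "pdb_id": "7P66",
    "disease": "globular glial tauopathy",
    "modeled_ranges": [[272, 379]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 309, "atom_a": "CG1", "res_b": 296, "atom_b": "CB", "distance": 4.4, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 309, "atom_a": "CG2", "res_b": 297, "atom_b": "CD1", "distance": 4.2, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "OH", "res_b": 348, "atom_b": "OD1", "distance": 3.0, "type": "hbond"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "CD1", "res_b": 354, "atom_b": "CD1", "distance": 4.3, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 311, "atom_a": "NZ", "res_b": 348, "atom_b": "OD2", "distance": 3.0, "type": "hbond"}
    ]
  },
  "GPT": {
    "pdb_id": "7P6A",
    "disease": "limbic-predominant neuronal inclusion body 4R tauopathy (GGT-PSP-tau)",
    "modeled_ranges": [[272, 381]],
    "planted_contacts": [
      {"motif": "PHF6", "res_a": 309, "atom_a": "CG1", "res_b": 350, "atom_b": "CG1", "distance": 4.2, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "CD2", "res_b": 297, "atom_b": "CG2", "distance": 4.4, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 310, "atom_a": "OH", "res_b": 295, "atom_b": "OD1", "distance": 3.1, "type": "hbond"},
      {"motif": "PHF6", "res_a": 311, "atom_a": "CD", "res_b": 350, "atom_b": "CG2", "distance": 4.6, "type": "hydrophobic"},
      {"motif": "PHF6", "res_a": 311, "atom_a": "NZ", "res_b": 348, "atom_b": "OD1", "distance": 2.9, "type": "hbond"}
    ]
  }
}
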