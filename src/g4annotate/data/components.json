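{
  "_comment": "Chemical-component table: residue code -> parent base. Standard codes map to themselves (unmodified); everything else is a modified nucleotide mapped to its parent.",
  "standard": {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T"
  },
  "modified": {
    "BGM": "G", "BRG": "G", "8OG": "G", "OGG": "G", "GF2": "G", "LCG": "G",
    "GFL": "G", "2PR": "G", "7DG": "G", "PGN": "G", "6OG": "G", "O2G": "G",
    "MRG": "G", "M2G": "G", "OMG": "G", "1MG": "G", "2MG": "G", "7MG": "G",
    "IGU": "G", "XUG": "G", "GNE": "G", "GTP": "G", "GDP": "G", "GMP": "G",
    "5CM": "C", "OMC": "C", "5MC": "C", "CBR": "C", "CFL": "C",
    "BRU": "U", "5BU": "U", "OMU": "U", "UFT": "U", "PSU": "U", "UR3": "U",
    "5IU": "U", "DUZ": "U",
    "1MA": "A", "MA6": "A", "OMA": "A", "A2M": "A", "6MA": "A",
    "2AP": "A", "PRN": "A", "3DA": "A",
    "T49": "T", "64T": "T", "2BT": "T", "LCT": "T"
  }
}
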