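{
  "_comment": "Number of hydrogens bonded to each heavy atom of the standard biopolymer residues (neutral pH protonation; HIS entries per tautomer). Used for united-atom scattering groups when a structure carries no explicit hydrogens. Terminal OH hydrogens (N/C termini, 5'-OH/3'-OH) are added programmatically.",
  "_version": 1,
  "_backbone_protein": {"N": 1, "CA": 1, "C": 0, "O": 0, "OXT": 0},
  "ALA": {"CB": 3},
  "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
  "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
  "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
  "CYS": {"CB": 2, "SG": 1},
  "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
  "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
  "GLY": {},
  "HIS": {"CB": 2, "CG": 0, "ND1": 0, "CD2": 1, "CE1": 1, "NE2": 1},
  "HISD": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 0},
  "HISE": {"CB": 2, "CG": 0, "ND1": 0, "CD2": 1, "CE1": 1, "NE2": 1},
  "HISP": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 1},
  "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
  "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
  "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
  "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
  "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
  "PRO": {"N": 0, "CB": 2, "CG": 2, "CD": 2},
  "SER": {"CB": 2, "OG": 1},
  "THR": {"CB": 1, "OG1": 1, "CG2": 3},
  "TRP": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1, "CE2": 0, "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
  "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 0, "OH": 1},
  "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
  "_backbone_nucleic": {"P": 0, "OP1": 0, "OP2": 0, "O5'": 0, "C5'": 2, "C4'": 1, "O4'": 0, "C3'": 1, "O3'": 0, "C1'": 1},
  "_sugar_rna": {"C2'": 1, "O2'": 1},
  "_sugar_dna": {"C2'": 2},
  "A": {"N9": 0, "C8": 1, "N7": 0, "C5": 0, "C6": 0, "N6": 2, "N1": 0, "C2": 1, "N3": 0, "C4": 0},
  "G": {"N9": 0, "C8": 1, "N7": 0, "C5": 0, "C6": 0, "O6": 0, "N1": 1, "C2": 0, "N2": 2, "N3": 0, "C4": 0},
  "C_base": {"N1": 0, "C2": 0, "O2": 0, "N3": 0, "C4": 0, "N4": 2, "C5": 1, "C6": 1},
  "U": {"N1": 0, "C2": 0, "O2": 0, "N3": 1, "C4": 0, "O4": 0, "C5": 1, "C6": 1},
  "T": {"N1": 0, "C2": 0, "O2": 0, "N3": 1, "C4": 0, "O4": 0, "C5": 0, "C7": 3, "C6": 1}
}
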