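"""Fixed chemical reference tables.

All geometry in the package is heavy-atom based; hydrogens present in an
input file are ignored except where noted (hydrogen-bond inference works on
donor/acceptor heavy atoms directly).
"""

from __future__ import annotations

# Canonical amino-acid ordering used for every 20x20 table in the package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Selenomethionine is silently mapped to methionine (SE -> SD); every other
# non-standard residue is treated as hetero.
NONSTANDARD_MAP = {"MSE": "MET"}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# van der Waals radii (A) by element, Bondi-style values.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
VDW_DEFAULT = 1.70

WATER_RADIUS = 1.4  # probe radius (A)
OCCLUSION_SHELL = 2.8  # water-diameter shell for occluded-surface rays (A)

# Maximum sidechain solvent-accessible areas (A^2) of residue X in an
# extended (phi=-139, psi=135) Gly-X-Gly tripeptide, computed once with the
# package's own dot-SASA engine (960 dots/atom, 1.4 A probe) and frozen
# here so relative accessibilities are self-consistent with it.  Glycine
# uses CA as its sidechain proxy.
MAX_SIDECHAIN_AREA = {
    "A": 38.7, "R": 178.8, "N": 92.8, "D": 90.9, "C": 72.8,
    "Q": 120.2, "E": 119.0, "G": 26.8, "H": 119.8, "I": 112.6,
    "L": 105.9, "K": 137.1, "M": 118.3, "F": 136.5, "P": 69.6,
    "S": 58.4, "T": 85.1, "W": 164.5, "Y": 154.3, "V": 85.4,
}

# Sidechain hydrogen-bond donor / acceptor heavy atoms.
SIDECHAIN_DONORS = {
    "S": {"OG"}, "T": {"OG1"}, "Y": {"OH"}, "C": {"SG"},
    "N": {"ND2"}, "Q": {"NE2"}, "K": {"NZ"},
    "R": {"NE", "NH1", "NH2"}, "H": {"ND1", "NE2"}, "W": {"NE1"},
}
SIDECHAIN_ACCEPTORS = {
    "S": {"OG"}, "T": {"OG1"}, "Y": {"OH"}, "C": {"SG"},
    "N": {"OD1"}, "Q": {"OE1"},
    "D": {"OD1", "OD2"}, "E": {"OE1", "OE2"},
    "H": {"ND1", "NE2"}, "M": {"SD"},
}

# Heavy-atom sidechain compositions of the 20 standard residues (backbone
# N, CA, C, O excluded; glycine has none).
SIDECHAIN_ATOMS = {
    "A": ["CB"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "N": ["CB", "CG", "OD1", "ND2"],
    "D": ["CB", "CG", "OD1", "OD2"],
    "C": ["CB", "SG"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"],
    "G": [],
    "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["CB", "CG1", "CG2", "CD1"],
    "L": ["CB", "CG", "CD1", "CD2"],
    "K": ["CB", "CG", "CD", "CE", "NZ"],
    "M": ["CB", "CG", "SD", "CE"],
    "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "P": ["CB", "CG", "CD"],
    "S": ["CB", "OG"],
    "T": ["CB", "OG1", "CG2"],
    "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "V": ["CB", "CG1", "CG2"],
}

# Sidechain chi-angle definitions (atom quadruples) and the single
# most-common rotamer used for deterministic mutant sidechain placement.
CHI_ATOMS = {
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
}

ROTAMER_CHI = {
    "R": (-67.0, 180.0, 180.0, 180.0),
    "N": (-65.0, -20.0),
    "D": (-70.0, -15.0),
    "C": (-65.0,),
    "Q": (-67.0, 180.0, -25.0),
    "E": (-67.0, 180.0, -10.0),
    "H": (-65.0, -70.0),
    "I": (-65.0, 170.0),
    "L": (-65.0, 175.0),
    "K": (-67.0, 180.0, 180.0, 180.0),
    "M": (-67.0, 180.0, 75.0),
    "F": (-65.0, 90.0),
    "S": (62.0,),
    "T": (-60.0,),
    "W": (-65.0, 95.0),
    "Y": (-65.0, 90.0),
    "V": (175.0,),
}


def vdw_radius(element: str) -> float:
    """van der Waals radius for an element symbol (A)."""
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)
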