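"""Amino-acid chemistry tables: topology templates, torsion bookkeeping, charges.

Sidechain geometry is encoded as an internal-coordinate template per residue
type: each heavy atom is placed relative to three previously placed atoms
(parent, angle reference, dihedral reference) with an ideal bond length,
angle, and a dihedral that is either fixed or an offset from a sampled chi
angle.  Bond lengths/angles are standard idealised values; this is a rigid
idealised-geometry model, not a force-field parameterisation.

The chi-count table drives rotatable-bond counting: backbone phi (residues
2..n) and psi (residues 1..n-1), sidechain chis, plus one C-terminal carboxyl
rotation; omega amide torsions are excluded and proline contributes neither
phi nor chi.
"""

from __future__ import annotations

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

STANDARD_RESIDUES = frozenset(ONE_TO_THREE.values())

#: Number of sampled sidechain chi torsions per residue type.
CHI_COUNT = {
    "ALA": 0, "GLY": 0, "PRO": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "ILE": 2, "LEU": 2, "ASP": 2, "ASN": 2, "HIS": 2, "PHE": 2,
    "TYR": 2, "TRP": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

#: Residue types with nucleophilic sidechains, excluded as segment N-termini
#: during fragmentation (they would compete with the backbone amine in the
#: modelled amide-forming reaction).
FORBIDDEN_NTERM = frozenset({"TYR", "CYS", "SER", "THR", "ASN", "GLN"})

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

# Sidechain internal-coordinate templates.
# Entry: (name, element, parent, angle_ref, dihedral_ref, bond, angle, tau)
# tau is ("chi", k, offset_degrees) or ("fix", degrees).  The atom is bonded
# to its parent; ring-closing bonds that the tree cannot express are listed
# in EXTRA_BONDS.
_CB = ("CB", "C", "CA", "N", "C", 1.53, 110.5, ("fix", -122.5))

SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "O", "CB", "CA", "N", 1.42, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, ("SG", "S", "CB", "CA", "N", 1.81, 114.0, ("chi", 1, 0.0))],
    "THR": [_CB,
            ("OG1", "O", "CB", "CA", "N", 1.43, 109.6, ("chi", 1, 0.0)),
            ("CG2", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120.0))],
    "VAL": [_CB,
            ("CG1", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, 0.0)),
            ("CG2", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, 120.0))],
    "LEU": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.53, 116.3, ("chi", 1, 0.0)),
            ("CD1", "C", "CG", "CB", "CA", 1.52, 110.7, ("chi", 2, 0.0)),
            ("CD2", "C", "CG", "CB", "CA", 1.52, 110.7, ("chi", 2, 120.0))],
    "ILE": [_CB,
            ("CG1", "C", "CB", "CA", "N", 1.53, 110.4, ("chi", 1, 0.0)),
            ("CG2", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120.0)),
            ("CD1", "C", "CG1", "CB", "CA", 1.51, 113.9, ("chi", 2, 0.0))],
    "MET": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.52, 114.1, ("chi", 1, 0.0)),
            ("SD", "S", "CG", "CB", "CA", 1.81, 112.7, ("chi", 2, 0.0)),
            ("CE", "C", "SD", "CG", "CB", 1.79, 100.9, ("chi", 3, 0.0))],
    # Proline ring: fixed endo-pucker internal coordinates; CD-N closure bond
    # recorded in EXTRA_BONDS.
    "PRO": [("CB", "C", "CA", "N", "C", 1.53, 103.0, ("fix", -125.0)),
            ("CG", "C", "CB", "CA", "N", 1.50, 104.5, ("fix", 7.0)),
            ("CD", "C", "CG", "CB", "CA", 1.51, 105.6, ("fix", -31.0))],
    "PHE": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0.0)),
            ("CD1", "C", "CG", "CB", "CA", 1.39, 120.8, ("chi", 2, 0.0)),
            ("CD2", "C", "CG", "CB", "CA", 1.39, 120.8, ("chi", 2, 180.0)),
            ("CE1", "C", "CD1", "CG", "CB", 1.39, 120.0, ("fix", 180.0)),
            ("CE2", "C", "CD2", "CG", "CB", 1.39, 120.0, ("fix", 180.0)),
            ("CZ", "C", "CE1", "CD1", "CG", 1.39, 120.0, ("fix", 0.0))],
    "TYR": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.51, 113.9, ("chi", 1, 0.0)),
            ("CD1", "C", "CG", "CB", "CA", 1.39, 120.8, ("chi", 2, 0.0)),
            ("CD2", "C", "CG", "CB", "CA", 1.39, 120.8, ("chi", 2, 180.0)),
            ("CE1", "C", "CD1", "CG", "CB", 1.39, 120.0, ("fix", 180.0)),
            ("CE2", "C", "CD2", "CG", "CB", 1.39, 120.0, ("fix", 180.0)),
            ("CZ", "C", "CE1", "CD1", "CG", 1.39, 120.0, ("fix", 0.0)),
            ("OH", "O", "CZ", "CE1", "CD1", 1.38, 120.0, ("fix", 180.0))],
    "TRP": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.50, 113.6, ("chi", 1, 0.0)),
            ("CD1", "C", "CG", "CB", "CA", 1.37, 127.0, ("chi", 2, 0.0)),
            ("CD2", "C", "CG", "CB", "CA", 1.43, 126.6, ("chi", 2, 180.0)),
            ("NE1", "N", "CD1", "CG", "CB", 1.38, 110.2, ("fix", 180.0)),
            ("CE2", "C", "CD2", "CG", "CB", 1.41, 107.2, ("fix", 180.0)),
            ("CE3", "C", "CD2", "CG", "CB", 1.40, 133.9, ("fix", 0.0)),
            ("CZ2", "C", "CE2", "CD2", "CG", 1.40, 122.4, ("fix", 180.0)),
            ("CZ3", "C", "CE3", "CD2", "CG", 1.39, 118.7, ("fix", 180.0)),
            ("CH2", "C", "CZ2", "CE2", "CD2", 1.37, 117.5, ("fix", 0.0))],
    "ASP": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.52, 113.1, ("chi", 1, 0.0)),
            ("OD1", "O", "CG", "CB", "CA", 1.25, 118.2, ("chi", 2, 0.0)),
            ("OD2", "O", "CG", "CB", "CA", 1.25, 118.2, ("chi", 2, 180.0))],
    "ASN": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.52, 112.7, ("chi", 1, 0.0)),
            ("OD1", "O", "CG", "CB", "CA", 1.23, 120.8, ("chi", 2, 0.0)),
            ("ND2", "N", "CG", "CB", "CA", 1.33, 116.4, ("chi", 2, 180.0))],
    "GLU": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", "CG", "CB", "CA", 1.52, 113.1, ("chi", 2, 0.0)),
            ("OE1", "O", "CD", "CG", "CB", 1.25, 118.2, ("chi", 3, 0.0)),
            ("OE2", "O", "CD", "CG", "CB", 1.25, 118.2, ("chi", 3, 180.0))],
    "GLN": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", "CG", "CB", "CA", 1.52, 112.7, ("chi", 2, 0.0)),
            ("OE1", "O", "CD", "CG", "CB", 1.23, 120.8, ("chi", 3, 0.0)),
            ("NE2", "N", "CD", "CG", "CB", 1.33, 116.4, ("chi", 3, 180.0))],
    "LYS": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2, 0.0)),
            ("CE", "C", "CD", "CG", "CB", 1.52, 111.3, ("chi", 3, 0.0)),
            ("NZ", "N", "CE", "CD", "CG", 1.49, 111.9, ("chi", 4, 0.0))],
    "ARG": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", "C", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2, 0.0)),
            ("NE", "N", "CD", "CG", "CB", 1.46, 112.0, ("chi", 3, 0.0)),
            ("CZ", "C", "NE", "CD", "CG", 1.33, 124.2, ("chi", 4, 0.0)),
            ("NH1", "N", "CZ", "NE", "CD", 1.33, 120.0, ("fix", 0.0)),
            ("NH2", "N", "CZ", "NE", "CD", 1.33, 120.0, ("fix", 180.0))],
    "HIS": [_CB,
            ("CG", "C", "CB", "CA", "N", 1.49, 113.8, ("chi", 1, 0.0)),
            ("ND1", "N", "CG", "CB", "CA", 1.38, 122.7, ("chi", 2, 0.0)),
            ("CD2", "C", "CG", "CB", "CA", 1.35, 131.0, ("chi", 2, 180.0)),
            ("CE1", "C", "ND1", "CG", "CB", 1.32, 109.0, ("fix", 180.0)),
            ("NE2", "N", "CD2", "CG", "CB", 1.35, 107.0, ("fix", 180.0))],
}

#: Ring-closure bonds the placement tree cannot express (atom-name pairs).
EXTRA_BONDS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

#: Sidechain formal charge at physiological pH (7.4).
SIDECHAIN_FORMAL_CHARGE = {
    "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1,
}

#: Sidechain hydrogen-bond donor heavy atoms (implicit-H model, pH 7.4).
SIDECHAIN_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["ND2"], "GLN": ["NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "HIS": ["NE2"], "TRP": ["NE1"],
}

#: Sidechain hydrogen-bond acceptor heavy atoms.
SIDECHAIN_ACCEPTORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "ASN": ["OD1"], "GLN": ["OE1"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "HIS": ["ND1"],
}

#: Chemically equivalent sidechain atom pairs, swapped jointly per group when
#: minimising RMSD (ring flips and carboxylate/guanidinium symmetry).
SYMMETRY_GROUPS: dict[str, list[list[tuple[str, str]]]] = {
    "PHE": [[("CD1", "CD2"), ("CE1", "CE2")]],
    "TYR": [[("CD1", "CD2"), ("CE1", "CE2")]],
    "ASP": [[("OD1", "OD2")]],
    "GLU": [[("OE1", "OE2")]],
    "ARG": [[("NH1", "NH2")]],
}

#: Baseline partial charge by element; per-residue totals are then shifted
#: uniformly so each residue sums to its formal charge (a coarse but
#: self-consistent table for the surrogate electrostrostatic term).
BASELINE_PARTIAL = {"N": -0.35, "O": -0.40, "C": 0.08, "S": -0.15,
                    "CL": -0.10}

#: Covalent radii (A) for distance-based bond perception.
COVALENT_RADII = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "CL": 0.99,
                  "H": 0.31}

#: Apolar sidechain carbon atoms used to plant hydrophobic contacts.
HYDROPHOBIC_ATOMS = {
    "ALA": ["CB"], "VAL": ["CG1", "CG2"], "LEU": ["CD1", "CD2"],
    "ILE": ["CD1", "CG2"], "MET": ["CE"], "PHE": ["CZ", "CE1", "CE2"],
    "TRP": ["CZ2", "CH2", "CZ3"], "PRO": ["CG"],
}


def chi_count(resname: str) -> int:
    """Sidechain torsion count for a residue type; raises on non-standard."""
    try:
        return CHI_COUNT[resname]
    except KeyError:
        raise UnsupportedResidueError(resname) from None


class UnsupportedResidueError(ValueError):
    """Raised when a residue type is outside the standard 20."""

    def __init__(self, resname: str):
        super().__init__(f"unsupported residue type: {resname!r}")
        self.resname = resname
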