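"""Amino-acid reference tables.

Static chemistry used across the package: one/three-letter codes,
Kyte–Doolittle hydropathy, formal charges, hydrogen-bond donor/acceptor
heavy atoms, van der Waals radii, and an idealized heavy-atom topology
(internal-coordinate records) used to realize side chains from chi
torsions. Geometry values are idealized averages, adequate for the
desk-scale structure builder; they are not refined crystallographic
restraints.
"""

from __future__ import annotations

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_TOKEN = "-"

#: Kyte–Doolittle hydropathy, range [-4.5, 4.5].
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Formal charges on representative side-chain atoms (physiological pH).
FORMAL_CHARGES = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "CZ"): 1.0,
    ("ASP", "CG"): -1.0,
    ("GLU", "CD"): -1.0,
}

#: Heavy atoms that carry donatable protons / lone-pair acceptors.
HBOND_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("TRP", "NE1"), ("HIS", "ND1"), ("HIS", "NE2"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"),
    ("ARG", "NH2"),
}
HBOND_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70

# Idealized backbone internal geometry (lengths in Angstrom, angles in deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Side-chain topology beyond CB.  Each record: (atom, ref3, ref2, ref1,
# bond length, bond angle deg, torsion).  The torsion is either a fixed
# value in degrees or ("chi", k, offset_deg): chi angle k plus offset.
# Atom placed by NeRF off ref1, with angle at ref2 and dihedral
# ref3-ref2-ref1-atom.
_c = lambda k, off=0.0: ("chi", k, off)
SIDE_CHAIN_TOPOLOGY = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "N", "CA", "CB", 1.42, 110.5, _c(1))],
    "CYS": [("SG", "N", "CA", "CB", 1.81, 114.0, _c(1))],
    "THR": [("OG1", "N", "CA", "CB", 1.43, 109.5, _c(1)),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, _c(1, 120.0))],
    "VAL": [("CG1", "N", "CA", "CB", 1.52, 110.5, _c(1)),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, _c(1, 122.0))],
    "LEU": [("CG", "N", "CA", "CB", 1.53, 116.3, _c(1)),
            ("CD1", "CA", "CB", "CG", 1.52, 110.5, _c(2)),
            ("CD2", "CA", "CB", "CG", 1.52, 110.5, _c(2, 122.0))],
    "ILE": [("CG1", "N", "CA", "CB", 1.53, 110.5, _c(1)),
            ("CG2", "N", "CA", "CB", 1.53, 110.5, _c(1, -122.0)),
            ("CD1", "CA", "CB", "CG1", 1.52, 113.8, _c(2))],
    "MET": [("CG", "N", "CA", "CB", 1.52, 114.1, _c(1)),
            ("SD", "CA", "CB", "CG", 1.81, 112.7, _c(2)),
            ("CE", "CB", "CG", "SD", 1.79, 100.9, _c(3))],
    "PRO": [("CG", "N", "CA", "CB", 1.49, 104.5, _c(1)),
            ("CD", "CA", "CB", "CG", 1.50, 105.5, _c(2))],
    "PHE": [("CG", "N", "CA", "CB", 1.50, 113.8, _c(1)),
            ("CD1", "CA", "CB", "CG", 1.39, 120.0, _c(2)),
            ("CD2", "CA", "CB", "CG", 1.39, 120.0, _c(2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0)],
    "TYR": [("CG", "N", "CA", "CB", 1.51, 113.8, _c(1)),
            ("CD1", "CA", "CB", "CG", 1.39, 120.0, _c(2)),
            ("CD2", "CA", "CB", "CG", 1.39, 120.0, _c(2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.38, 120.0, 180.0)],
    "TRP": [("CG", "N", "CA", "CB", 1.50, 113.8, _c(1)),
            ("CD1", "CA", "CB", "CG", 1.37, 127.0, _c(2)),
            ("CD2", "CA", "CB", "CG", 1.43, 126.6, _c(2, 180.0)),
            ("NE1", "CB", "CG", "CD1", 1.38, 110.2, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.41, 107.2, 180.0),
            ("CE3", "CB", "CG", "CD2", 1.40, 133.9, 0.0),
            ("CZ2", "CG", "CD2", "CE2", 1.40, 122.4, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.39, 118.6, 180.0),
            ("CH2", "CD2", "CE2", "CZ2", 1.37, 117.5, 0.0)],
    "ASP": [("CG", "N", "CA", "CB", 1.52, 113.0, _c(1)),
            ("OD1", "CA", "CB", "CG", 1.25, 118.5, _c(2)),
            ("OD2", "CA", "CB", "CG", 1.25, 118.5, _c(2, 180.0))],
    "ASN": [("CG", "N", "CA", "CB", 1.52, 113.0, _c(1)),
            ("OD1", "CA", "CB", "CG", 1.23, 120.8, _c(2)),
            ("ND2", "CA", "CB", "CG", 1.33, 116.4, _c(2, 180.0))],
    "GLU": [("CG", "N", "CA", "CB", 1.52, 114.1, _c(1)),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, _c(2)),
            ("OE1", "CB", "CG", "CD", 1.25, 118.5, _c(3)),
            ("OE2", "CB", "CG", "CD", 1.25, 118.5, _c(3, 180.0))],
    "GLN": [("CG", "N", "CA", "CB", 1.52, 114.1, _c(1)),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, _c(2)),
            ("OE1", "CB", "CG", "CD", 1.23, 120.8, _c(3)),
            ("NE2", "CB", "CG", "CD", 1.33, 116.4, _c(3, 180.0))],
    "LYS": [("CG", "N", "CA", "CB", 1.52, 114.1, _c(1)),
            ("CD", "CA", "CB", "CG", 1.52, 111.3, _c(2)),
            ("CE", "CB", "CG", "CD", 1.52, 111.3, _c(3)),
            ("NZ", "CG", "CD", "CE", 1.49, 111.9, _c(4))],
    "ARG": [("CG", "N", "CA", "CB", 1.52, 114.1, _c(1)),
            ("CD", "CA", "CB", "CG", 1.52, 111.3, _c(2)),
            ("NE", "CB", "CG", "CD", 1.46, 111.5, _c(3)),
            ("CZ", "CG", "CD", "NE", 1.33, 124.2, _c(4)),
            ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0)],
    "HIS": [("CG", "N", "CA", "CB", 1.50, 113.8, _c(1)),
            ("ND1", "CA", "CB", "CG", 1.38, 122.7, _c(2)),
            ("CD2", "CA", "CB", "CG", 1.36, 131.0, _c(2, 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.32, 109.2, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.37, 107.2, 180.0)],
}

N_CHI = {
    "ALA": 0, "GLY": 0, "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "PRO": 2, "PHE": 2, "TYR": 2, "TRP": 2,
    "ASP": 2, "ASN": 2, "HIS": 2, "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}
MAX_CHI = 4


def heavy_atom_names(resname: str) -> list[str]:
    """Ordered heavy-atom names for a residue (backbone first)."""
    names = ["N", "CA", "C", "O"]
    if resname != "GLY":
        names.append("CB")
    names.extend(rec[0] for rec in SIDE_CHAIN_TOPOLOGY[resname])
    return names


def heavy_atom_count(resname: str) -> int:
    return len(heavy_atom_names(resname))


def element_of(atom_name: str) -> str:
    """Element symbol from a PDB-style heavy-atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position of atom d bonded to c with angle b-c-d
    and dihedral a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    tors = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # collinear references; pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(tors),
        bond * np.sin(angle) * np.sin(tors),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
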