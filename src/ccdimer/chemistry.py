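"""Amino-acid reference data shared by all analysis modules.

Heavy-atom internal-coordinate templates (z-matrix style), a compact
most-common rotamer table, Bondi van der Waals radii, donor/acceptor and
apolar atom classes, formal side-chain charges, and aromatic ring
definitions.  All geometry values are standard ideal values (Engh-Huber
style bond lengths/angles); nothing here is fitted to data.
"""

from __future__ import annotations

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
STANDARD_AA = set(AA_3TO1)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Ideal backbone geometry (lengths in Angstrom, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

# CB placement: refs (N, C, CA); torsion N-C-CA-CB gives L-chirality.
CB_BOND = 1.532
CB_ANGLE = 110.1          # C-CA-CB
CB_TORSION = -122.6       # N-C-CA-CB

# Side-chain z-matrix: name -> list of
#   (atom, (ref_a, ref_b, ref_c), bond, angle_deg, torsion)
# torsion is a float (fixed) or ("chi", k, offset_deg) meaning chi_k+offset.
# NeRF placement: bond = |ref_c - atom|, angle = ref_b/ref_c/atom,
# torsion = dihedral(ref_a, ref_b, ref_c, atom).
_chi = lambda k, off=0.0: ("chi", k, off)

SIDECHAIN_ZMAT: dict[str, list] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.4, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.4, _chi(1, 122.0))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.524, 110.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.525, 110.4, _chi(2, 122.0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "MET": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3))],
    "PRO": [("CG", ("N", "CA", "CB"), 1.492, 104.5, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.503, 106.1, _chi(2))],
    "PHE": [("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.372, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.512, 113.9, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, _chi(2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.7, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "ARG": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
            ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.354, 131.0, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
            ("NE2", ("CG", "ND1", "CE1"), 1.326, 108.4, 0.0)],
}

# Most-common chi rotamers per residue (degrees), tried in order during
# side-chain placement; a chi1 grid scan backs them up when all clash.
ROTAMERS: dict[str, list[tuple]] = {
    "GLY": [()], "ALA": [()],
    "SER": [(64.0,), (-66.0,), (178.0,)],
    "CYS": [(-65.0,), (178.0,), (64.0,)],
    "THR": [(62.0,), (-60.0,), (180.0,)],
    "VAL": [(175.0,), (-60.0,), (64.0,)],
    "LEU": [(-65.0, 175.0), (180.0, 65.0), (-85.0, 65.0), (65.0, 175.0)],
    "ILE": [(-65.0, 170.0), (-57.0, -60.0), (62.0, 170.0), (180.0, 165.0)],
    "MET": [(-65.0, -65.0, -70.0), (-65.0, 180.0, 180.0),
            (180.0, 180.0, 75.0), (180.0, 180.0, 180.0)],
    "PRO": [(29.0, -37.0), (-27.0, 39.0)],
    "PHE": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0)],
    "TYR": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0)],
    "TRP": [(-65.0, 95.0), (180.0, -105.0), (62.0, -90.0)],
    "ASP": [(-70.0, -15.0), (180.0, 15.0), (62.0, -15.0)],
    "ASN": [(-65.0, -20.0), (180.0, 30.0), (62.0, -75.0)],
    "GLU": [(-65.0, 180.0, -10.0), (180.0, 180.0, 0.0), (-65.0, -65.0, -40.0)],
    "GLN": [(-65.0, 180.0, -25.0), (180.0, 180.0, 0.0), (-65.0, -65.0, -40.0)],
    "LYS": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-65.0, -65.0, 180.0, 180.0)],
    "ARG": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-65.0, -65.0, 180.0, 180.0), (-65.0, 180.0, 65.0, 85.0)],
    "HIS": [(-65.0, -70.0), (180.0, 60.0), (62.0, -75.0)],
}


def sidechain_heavy_atoms(resname: str) -> list[str]:
    """Heavy side-chain atom names (CB onward) for a standard residue."""
    names = [] if resname == "GLY" else ["CB"]
    names.extend(entry[0] for entry in SIDECHAIN_ZMAT.get(resname, []))
    return names


def heavy_atom_names(resname: str) -> list[str]:
    return list(BACKBONE_ATOMS) + sidechain_heavy_atoms(resname)


# Bondi van der Waals radii (Angstrom)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}


def infer_element(atom_name: str) -> str:
    """PDB v3 style element inference from an atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in ("H", "D"):
        return "H"
    two = stripped[:2].upper()
    if two == "SE":
        return "SE"
    return stripped[0].upper()


# Apolar side-chain carbon/sulfur positions (not adjacent to N/O) used by
# the hydrophobic-contact classifier.
APOLAR_ATOMS: dict[str, frozenset] = {k: frozenset(v) for k, v in {
    "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"], "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "PRO": ["CB", "CG"], "CYS": ["CB", "SG"], "LYS": ["CB", "CG", "CD"],
    "ARG": ["CB", "CG"], "GLU": ["CB", "CG"], "GLN": ["CB", "CG"],
    "ASP": ["CB"], "ASN": ["CB"], "THR": ["CG2"], "HIS": ["CB"],
    "SER": [], "GLY": [],
}.items()}

# Hydrogen-bond donor heavy atoms mapped to their antecedent atom
# (used to approximate the D-H direction when no explicit H is present).
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CE1"}, "TRP": {"NE1": "CD1"},
    "CYS": {}, "GLY": {},
}

SIDECHAIN_ACCEPTORS: dict[str, tuple] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

# Salt-bridge partner atoms
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

FORMAL_CHARGE = {"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1, "HIS": 0}

# Aromatic rings used for plane fits / centroids
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
AROMATIC_RESIDUES = frozenset(RING_ATOMS)
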