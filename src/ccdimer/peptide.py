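"""Internal-coordinate peptide construction (NeRF chain extension).

Builds backbones from (phi, psi, omega) torsion lists with ideal bond
geometry and attaches heavy-atom side chains from the z-matrix templates
in :mod:`ccdimer.chemistry`.  Used by the synthetic-structure generator
and by the in-silico mutagenesis routine.
"""

from __future__ import annotations

import numpy as np

from . import chemistry as chem
from .structure import Atom, Model, Residue


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D given references A, B, C (NeRF).

    ``bond`` = |C-D|, ``angle`` = angle(B, C, D), ``torsion`` =
    dihedral(A, B, C, D).
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # colinear references: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(n_res: int, phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O coordinates for a chain of ``n_res`` residues.

    ``phi[i]`` is undefined for i=0 and ``psi[i]`` for the last residue;
    values given there are ignored.  Returns arrays of shape (n_res, 3).
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    omega = np.full(n_res, 180.0) if omega is None else np.asarray(omega, float)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    # seed the first residue in a canonical pose
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([chem.BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(chem.ANGLE_N_CA_C)
    C[0] = CA[0] + chem.BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                              chem.BOND_C_N, chem.ANGLE_CA_C_N, psi[i - 1])
            CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                               chem.BOND_N_CA, chem.ANGLE_C_N_CA, omega[i - 1])
            C[i] = place_atom(C[i - 1], N[i], CA[i],
                              chem.BOND_CA_C, chem.ANGLE_N_CA_C, phi[i])
    for i in range(n_res):
        # carbonyl O in the peptide plane: torsion N-CA-C-O = psi + 180
        psi_i = psi[i] if i < n_res - 1 else -40.0
        O[i] = place_atom(N[i], CA[i], C[i],
                          chem.BOND_C_O, chem.ANGLE_CA_C_O, psi_i + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    return place_atom(n, c, ca, chem.CB_BOND, chem.CB_ANGLE, chem.CB_TORSION)


def build_sidechain(resname: str, n: np.ndarray, ca: np.ndarray,
                    c: np.ndarray, chis: tuple | None = None) -> dict[str, np.ndarray]:
    """Heavy side-chain atom coordinates (CB onward) for one residue.

    ``chis`` overrides the first rotamer in the built-in table.
    """
    if resname not in chem.SIDECHAIN_ZMAT:
        raise ValueError(f"unknown residue {resname!r}")
    pos: dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c}
    if resname == "GLY":
        return {}
    pos["CB"] = place_cb(n, ca, c)
    out = {"CB": pos["CB"]}
    if chis is None:
        chis = chem.ROTAMERS[resname][0]
    for name, refs, bond, angle, tors in chem.SIDECHAIN_ZMAT[resname]:
        if isinstance(tors, tuple):
            _, k, off = tors
            t = (chis[k - 1] if k - 1 < len(chis) else 180.0) + off
        else:
            t = tors
        xyz = place_atom(pos[refs[0]], pos[refs[1]], pos[refs[2]], bond, angle, t)
        pos[name] = xyz
        out[name] = xyz
    return out


def build_peptide(sequence: str, phi: np.ndarray, psi: np.ndarray,
                  chain_id: str = "A", start_number: int = 1,
                  with_sidechains: bool = True,
                  model_id: int = 1) -> Model:
    """A full heavy-atom peptide model from sequence and backbone torsions.

    Side chains use the first (most common) rotamer of each residue; pass
    ``with_sidechains=False`` for a backbone+CB-only chain.
    """
    n_res = len(sequence)
    bb = build_backbone(n_res, phi, psi)
    residues = []
    for i, aa in enumerate(sequence):
        resname = chem.AA_1TO3.get(aa.upper())
        if resname is None:
            raise ValueError(f"non-standard amino-acid code {aa!r}")
        res = Residue(chain_id=chain_id, seq_number=start_number + i, name=resname)
        for bb_name in ("N", "CA", "C", "O"):
            res.add_atom(Atom(name=bb_name, element=bb_name[0],
                              coord=bb[bb_name][i]))
        if resname != "GLY":
            if with_sidechains:
                sc = build_sidechain(resname, bb["N"][i], bb["CA"][i], bb["C"][i])
            else:
                sc = {"CB": place_cb(bb["N"][i], bb["CA"][i], bb["C"][i])}
            for name, xyz in sc.items():
                res.add_atom(Atom(name=name, element=chem.infer_element(name),
                                  coord=xyz))
        residues.append(res)
    return Model(model_id=model_id, residues=residues)


def ideal_helix(sequence: str, chain_id: str = "A", start_number: int = 1,
                with_sidechains: bool = True) -> Model:
    """Ideal straight alpha-helix (phi=-57, psi=-47)."""
    n = len(sequence)
    return build_peptide(sequence, np.full(n, -57.0), np.full(n, -47.0),
                         chain_id=chain_id, start_number=start_number,
                         with_sidechains=with_sidechains)


def extended_chain(sequence: str, chain_id: str = "A", start_number: int = 1,
                   with_sidechains: bool = True) -> Model:
    """Fully extended (beta-like) chain (phi=-139, psi=135)."""
    n = len(sequence)
    return build_peptide(sequence, np.full(n, -139.0), np.full(n, 135.0),
                         chain_id=chain_id, start_number=start_number,
                         with_sidechains=with_sidechains)
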