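"""Secondary-structure assignment and helicity statistics.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
model; a residue is called alpha-helical (H) when consecutive i -> i+4
turns overlap, the minimal alpha rule of DSSP-style assignment.  Only
H vs not-H is distinguished rigorously: 3-10 and pi helices collapse
into coil, since the quantity of interest downstream is percentage
alpha-helicity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Model, Residue, Selection, StructureEnsemble, select

logger = logging.getLogger(__name__)

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol, standard Kabsch-Sander threshold
KS_FACTOR = 0.084 * 332.0   # q1*q2*332 in kcal/mol*Angstrom
CHAIN_BREAK_CA_CA = 4.5     # Angstrom
NH_BOND_LENGTH = 1.01


def _chain_segments(model: Model, chain_id: str) -> list[list[Residue]]:
    """Residues of one chain split into covalently continuous segments."""
    residues = model.chain_residues(chain_id)
    segments: list[list[Residue]] = []
    current: list[Residue] = []
    prev_ca = None
    for res in residues:
        ca = res.atom("CA")
        if ca is None:
            if current:
                segments.append(current)
                current = []
            prev_ca = None
            continue
        if prev_ca is not None and np.linalg.norm(ca.coord - prev_ca) > CHAIN_BREAK_CA_CA:
            segments.append(current)
            current = []
        current.append(res)
        prev_ca = ca.coord
    if current:
        segments.append(current)
    return segments


def amide_hydrogen(residue: Residue, prev_residue: Residue | None) -> np.ndarray | None:
    """Amide H position; explicit H if present, else built at 1.01 A.

    The built direction bisects the CA-N and C(prev)-N bond directions,
    pointing away from both -- the standard construction when NMR/MD
    files carry no protons.  Proline has no amide H.
    """
    if residue.name == "PRO":
        return None
    n = residue.atom("N")
    if n is None:
        return None
    for name in ("H", "HN", "H1"):
        h = residue.atom(name)
        if h is not None and np.linalg.norm(h.coord - n.coord) < 1.3:
            return h.coord
    if prev_residue is None:
        return None
    ca = residue.atom("CA")
    c_prev = prev_residue.atom("C")
    if ca is None or c_prev is None:
        return None
    v1 = ca.coord - n.coord
    v2 = c_prev.coord - n.coord
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return None
    direction = -(v1 / n1 + v2 / n2)
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        return None
    return n.coord + NH_BOND_LENGTH * direction / norm


def backbone_hbond_energy(donor_residue: Residue, acceptor_residue: Residue,
                          model: Model) -> float:
    """Kabsch-Sander N-H...O=C energy (kcal/mol); NaN when undefined.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN).  A bond is
    called when E < -0.5 kcal/mol.  Sequence-adjacent residues never
    bond (exclusion handled by the callers which enumerate pairs).
    """
    n = donor_residue.atom("N")
    c = acceptor_residue.atom("C")
    o = acceptor_residue.atom("O")
    if n is None or c is None or o is None:
        logger.debug("missing backbone atom for %s/%s", donor_residue.key,
                     acceptor_residue.key)
        return math.nan
    prev = _previous_residue(model, donor_residue)
    h = amide_hydrogen(donor_residue, prev)
    if h is None:
        return math.nan
    r_on = np.linalg.norm(o.coord - n.coord)
    r_ch = np.linalg.norm(c.coord - h)
    r_oh = np.linalg.norm(o.coord - h)
    r_cn = np.linalg.norm(c.coord - n.coord)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry
        return math.nan
    return float(KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _previous_residue(model: Model, residue: Residue) -> Residue | None:
    chain = model.chain_residues(residue.chain_id)
    for i, res in enumerate(chain):
        if res is residue:
            if i == 0:
                return None
            prev = chain[i - 1]
            ca_p, ca = prev.atom("CA"), residue.atom("CA")
            if ca_p is not None and ca is not None and \
                    np.linalg.norm(ca.coord - ca_p.coord) > CHAIN_BREAK_CA_CA:
                return None
            return prev
    return None


@dataclass
class SSAssignment:
    """Per-residue helix labels for one model."""
    labels: dict[tuple, str] = field(default_factory=dict)  # residue key -> H/E/C

    @property
    def helicity(self) -> float:
        if not self.labels:
            return 0.0
        n_h = sum(1 for v in self.labels.values() if v == "H")
        return n_h / len(self.labels)

    def label(self, chain_id: str, seq_number: int, icode: str = "") -> str:
        return self.labels.get((chain_id, seq_number, icode), "C")


def _segment_hbond_set(segment: list[Residue], model: Model) -> set[tuple[int, int]]:
    """(donor_index, acceptor_index) pairs bonded by the energy criterion."""
    bonds: set[tuple[int, int]] = set()
    n = len(segment)
    coords_ca = np.array([r.atom("CA").coord for r in segment])
    for i in range(n):          # donor
        for j in range(n):      # acceptor
            if abs(i - j) < 2:
                continue
            if np.linalg.norm(coords_ca[i] - coords_ca[j]) > 9.0:
                continue  # Kabsch-Sander bonds need close backbones
            e = backbone_hbond_energy(segment[i], segment[j], model)
            if not math.isnan(e) and e < HBOND_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_ss(model: Model) -> SSAssignment:
    """Alpha-helix assignment: residue i is H when two consecutive
    i -> i+4 turns cover it (minimal DSSP alpha rule)."""
    assignment = SSAssignment()
    for chain_id in model.chains:
        for segment in _chain_segments(model, chain_id):
            labels = ["C"] * len(segment)
            if len(segment) >= 5:
                bonds = _segment_hbond_set(segment, model)
                turn4 = [((i + 4, i) in bonds) for i in range(len(segment))]
                for i in range(1, len(segment) - 4):
                    if turn4[i - 1] and turn4[i]:
                        for j in range(i, i + 4):
                            labels[j] = "H"
            for res, lab in zip(segment, labels):
                has_backbone = all(res.atom(a) is not None for a in ("N", "CA", "C", "O"))
                if has_backbone:
                    assignment.labels[res.key] = lab
    return assignment


def helix_spans(assignment: SSAssignment, chain_id: str) -> list[tuple[int, int]]:
    """(first, last) residue numbers of contiguous H stretches in a chain."""
    spans: list[tuple[int, int]] = []
    start = prev = None
    keys = sorted((k for k in assignment.labels if k[0] == chain_id),
                  key=lambda k: (k[1], k[2]))
    for key in keys:
        if assignment.labels[key] == "H":
            if start is None:
                start = key[1]
            prev = key[1]
        else:
            if start is not None:
                spans.append((start, prev))
                start = None
    if start is not None:
        spans.append((start, prev))
    return spans


def ensemble_helicity(ensemble: StructureEnsemble,
                      selection: Selection | None = None
                      ) -> tuple[float, list[float]]:
    """Mean helicity over models, restricted to ``selection`` residues.

    Returns (mean, per-model series).  The denominator is the number of
    selected residues with defined labels.
    """
    series: list[float] = []
    for model in ensemble.models:
        assignment = assign_ss(model)
        if selection is None:
            keys = list(assignment.labels)
        else:
            atoms = select(model, selection)
            keys = sorted({(a.chain_id, a.seq_number, a.insertion_code)
                           for a in atoms})
            keys = [k for k in keys if k in assignment.labels]
        if not keys:
            raise ValueError("selection matches no residues with labels")
        n_h = sum(1 for k in keys if assignment.labels[k] == "H")
        series.append(n_h / len(keys))
    return float(np.mean(series)), series
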