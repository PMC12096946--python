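"""Synthetic coiled-coil structures with known ground truth.

Generates antiparallel (or parallel) two-chain coiled-coil dimers on a
Crick-style superhelical parameterization, Gaussian-perturbed
multi-model ensembles with a controllable per-residue fluctuation
profile, point mutants rebuilt from a compact rotamer table, and
progressive C-terminal unfolding ensembles.  Every structure passes the
package's own validation and round-trips through PDB.

The built-in sequences model the human PALB2 coiled-coil domain
(residues 6-42) and a synthetic BRCA1 coiled-coil-like partner chain
that carries the interface anchor residues at their published positions
(the real BRCA1 sequence is not bundled; see docs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chemistry as chem
from .dynamics import _kabsch
from .peptide import build_peptide, build_sidechain, dihedral, ideal_helix, place_atom, place_cb
from .structure import Atom, Model, Residue, StructureEnsemble

# Human PALB2 coiled-coil domain, residues 6-42 (author numbering).
PALB2CC_SEQUENCE = "GKPLSCEEKEKLKEKLAFLKREYSKTLARLQRAQRAE"
PALB2CC_START = 6
PALB2CC_HEPTAD_A_OFFSET = 4   # residue 10 sits at heptad position 'a'

# SYNTHETIC BRCA1 coiled-coil-like partner, residues 1380-1427: a
# leucine-zipper-style helix with the published PALB2-facing anchor
# residues (D1381, S1387, D1390, L1392, M1400, L1404, L1407, M1411,
# L1414, L1418, D1419) at their real positions, 4 positive and 7
# negative residues (net -3, negatively charged C-terminus).
BRCA1CC_SYNTHETIC_SEQUENCE = "SDQAEKLSQKDALAQQSKAQMQNSLAELQNSMAKLQNELDELQSALAQ"
BRCA1CC_START = 1380
BRCA1CC_HEPTAD_A_OFFSET = 6   # residue 1386 at 'a'
# antiparallel register: PALB2 index i packs against BRCA1 index 49 - i,
# which puts Y28 opposite L1407 (flanked by L1404/M1411) and K18 near
# E1417/D1419.
HETERODIMER_REGISTER_SUM = 49

CLASH_DISTANCE = 2.4  # A, heavy-atom clash threshold for rotamer placement


@dataclass
class CrickParams:
    """Superhelix parameters for a two-chain coiled-coil build."""
    superhelix_radius: float = 4.9     # A
    superhelix_pitch: float = 145.0    # A, left-handed supercoil
    residues_per_turn: float = 3.6     # minor helix
    rise_per_residue: float = 1.5      # A
    phase_a: float = 0.0               # deg, azimuth of chain A axis
    phase_b: float = 180.0             # deg, azimuth of chain B axis
    orientation: str = "antiparallel"  # or "parallel"
    heptad_a_offset_a: int = 0         # chain index of the first 'a' residue
    heptad_a_offset_b: int = 0
    z_shift_b: float = 0.0             # A, axial register shift of chain B
    # heptad indices (relative to 'a') whose side chains face the partner
    # chain; (0, 3) is the classic a/d core, (0, 4) an a/e interface as in
    # antiparallel coiled coils whose hydrophobic ladder alternates i+3/i+4
    interface_positions: tuple = (0, 3)

    def __post_init__(self):
        if self.superhelix_radius <= 0:
            raise ValueError("superhelix radius must be positive")
        if self.superhelix_pitch == 0:
            raise ValueError("superhelix pitch must be nonzero")
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class PerturbationProfile:
    """Per-residue isotropic Gaussian displacement magnitudes."""
    sigmas: np.ndarray   # A, one per residue of the model
    n_models: int
    seed: int
    per_atom: bool = False   # default: rigid per-residue displacement

    def __post_init__(self):
        self.sigmas = np.asarray(self.sigmas, float)
        if np.any(self.sigmas < 0):
            raise ValueError("sigmas must be non-negative")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


# ---------------------------------------------------------------------------
# coiled-coil construction

def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * k @ k


def _apply(model: Model, rot: np.ndarray, trans: np.ndarray) -> None:
    for atom in model.atoms():
        atom.coord = rot @ atom.coord + trans


def _align_helix_to_z(model: Model) -> None:
    """Rotate/translate a straight helix so its axis is +z through the origin."""
    ca = np.array([r.atom("CA").coord for r in model.residues])
    centers = np.array([ca[i:i + 4].mean(axis=0) for i in range(len(ca) - 3)])
    anchor = centers.mean(axis=0)
    _, _, vt = np.linalg.svd(centers - anchor)
    direction = vt[0]
    if np.dot(direction, centers[-1] - centers[0]) < 0:
        direction = -direction
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(direction, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3) if direction[2] > 0 else _rotation_about([1, 0, 0], math.pi)
    else:
        rot = _rotation_about(v / s, math.asin(min(s, 1.0))
                              if np.dot(direction, z) > 0
                              else math.pi - math.asin(min(s, 1.0)))
    _apply(model, rot, -rot @ anchor)


def _register_rotation(model: Model, heptad_a_offset: int,
                       interface_positions: tuple = (0, 3)) -> None:
    """Rotate about z so the mean interface side-chain azimuth points to -x
    (toward the superhelix axis after mapping)."""
    sines, cosines = [], []
    for i, res in enumerate(model.residues):
        if (i - heptad_a_offset) % 7 in interface_positions:
            atom = res.atom("CB") or res.atom("CA")
            x, y = atom.coord[0], atom.coord[1]
            theta = math.atan2(y, x)
            sines.append(math.sin(theta))
            cosines.append(math.cos(theta))
    if not sines:
        return
    mean_theta = math.atan2(np.mean(sines), np.mean(cosines))
    _apply(model, _rotation_about([0, 0, 1], math.pi - mean_theta), np.zeros(3))


def _supercoil(model: Model, radius: float, pitch: float, phase_deg: float) -> None:
    """Map a z-aligned straight helix onto a left-handed superhelical path.

    z is reinterpreted as arclength along the curved axis so the local
    rise per residue is preserved.
    """
    omega = 2.0 * math.pi / pitch
    stretch = math.sqrt(1.0 + (radius * omega) ** 2)
    phase = math.radians(phase_deg)
    for atom in model.atoms():
        x, y, z = atom.coord
        za = z / stretch
        theta = phase - omega * za          # left-handed supercoil
        c = np.array([radius * math.cos(theta), radius * math.sin(theta), za])
        tangent = np.array([radius * omega * math.sin(theta),
                            -radius * omega * math.cos(theta), 1.0]) / stretch
        normal = np.array([math.cos(theta), math.sin(theta), 0.0])
        binormal = np.cross(tangent, normal)
        atom.coord = c + x * normal + y * binormal


def build_coiled_coil(seq_a: str, seq_b: str, params: CrickParams | None = None,
                      sidechains: str = "cb",
                      start_number_a: int = 1, start_number_b: int = 1,
                      chain_ids: tuple[str, str] = ("A", "B")) -> Model:
    """Two-chain coiled-coil dimer on the Crick superhelix.

    ``sidechains='cb'`` places backbone + CB only; ``'full'`` builds
    complete heavy-atom side chains from the rotamer table.  The heptad
    register is recorded in the returned model as ``heptad_register``.
    """
    params = params or CrickParams()
    for seq in (seq_a, seq_b):
        if len(seq) < 7:
            raise ValueError("chains must have at least 7 residues")
    full = {"cb": False, "full": True}[sidechains]
    chains = []
    for seq, cid, start, phase, offset in (
            (seq_a, chain_ids[0], start_number_a, params.phase_a,
             params.heptad_a_offset_a),
            (seq_b, chain_ids[1], start_number_b, params.phase_b,
             params.heptad_a_offset_b)):
        m = ideal_helix(seq, chain_id=cid, start_number=start,
                        with_sidechains=full)
        _align_helix_to_z(m)
        _register_rotation(m, offset, params.interface_positions)
        if cid == chain_ids[1]:
            if params.orientation == "antiparallel":
                _apply(m, _rotation_about([1, 0, 0], math.pi), np.zeros(3))
            _apply(m, np.eye(3), np.array([0.0, 0.0, params.z_shift_b]))
        _supercoil(m, params.superhelix_radius, params.superhelix_pitch, phase)
        chains.append(m)
    residues = chains[0].residues + chains[1].residues
    model = Model(model_id=1, residues=residues)
    if full:
        model = _relax_sidechain_clashes(model)
    register = {}
    for (seq, start, offset) in ((seq_a, start_number_a, params.heptad_a_offset_a),
                                 (seq_b, start_number_b, params.heptad_a_offset_b)):
        for i in range(len(seq)):
            register[start + i] = "abcdefg"[(i - offset) % 7]
    model.heptad_register = register
    return model


def antiparallel_z_shift(n_a: int, n_b: int, register_sum: int,
                         rise: float = 1.5) -> float:
    """Axial shift of chain B so chain-A index i faces chain-B index
    register_sum - i in an antiparallel build."""
    return rise * (register_sum - (n_a - 1) / 2.0 - (n_b - 1) / 2.0)


def build_palb2_protomer(sidechains: str = "full") -> Model:
    """Single PALB2 coiled-coil-domain helix (chain A, residues 6-42)."""
    return ideal_helix(PALB2CC_SEQUENCE, chain_id="A",
                       start_number=PALB2CC_START,
                       with_sidechains=(sidechains == "full"))


def build_palb2_homodimer(sidechains: str = "full",
                          params: CrickParams | None = None) -> Model:
    """Antiparallel PALB2 coiled-coil homodimer (chains A and B)."""
    n = len(PALB2CC_SEQUENCE)
    # register_sum = n - 1 puts residue i opposite residue i (L24-L24',
    # Y28-Y28' at the interface center), which gives z_shift 0
    params = params or CrickParams(
        heptad_a_offset_a=PALB2CC_HEPTAD_A_OFFSET,
        heptad_a_offset_b=PALB2CC_HEPTAD_A_OFFSET,
        interface_positions=(0, 4),   # PALB2's ladder: L17/L24/T31 (a), L21/Y28/L35 (e)
        z_shift_b=antiparallel_z_shift(n, n, n - 1))
    return build_coiled_coil(PALB2CC_SEQUENCE, PALB2CC_SEQUENCE, params,
                             sidechains=sidechains,
                             start_number_a=PALB2CC_START,
                             start_number_b=PALB2CC_START)


def build_palb2_brca1_heterodimer(sidechains: str = "full") -> Model:
    """Antiparallel PALB2 (chain A) / synthetic BRCA1-like (chain B) dimer."""
    n_a = len(PALB2CC_SEQUENCE)
    n_b = len(BRCA1CC_SYNTHETIC_SEQUENCE)
    params = CrickParams(
        heptad_a_offset_a=PALB2CC_HEPTAD_A_OFFSET,
        heptad_a_offset_b=BRCA1CC_HEPTAD_A_OFFSET,
        interface_positions=(0, 4),
        z_shift_b=antiparallel_z_shift(n_a, n_b, HETERODIMER_REGISTER_SUM))
    return build_coiled_coil(PALB2CC_SEQUENCE, BRCA1CC_SYNTHETIC_SEQUENCE,
                             params, sidechains=sidechains,
                             start_number_a=PALB2CC_START,
                             start_number_b=BRCA1CC_START)


def _clashing_residues(model: Model) -> list[tuple[str, int, int]]:
    """(chain, resnum, clash count) for residues with heavy-atom overlaps."""
    from scipy.spatial import cKDTree
    atoms = [a for a in model.atoms() if not a.is_hydrogen]
    xyz = np.array([a.coord for a in atoms])
    tree = cKDTree(xyz)
    counts: dict[tuple[str, int], int] = {}
    for i, j in tree.query_pairs(CLASH_DISTANCE):
        ai, aj = atoms[i], atoms[j]
        if (ai.chain_id, ai.seq_number) == (aj.chain_id, aj.seq_number):
            continue
        if ai.chain_id == aj.chain_id and abs(ai.seq_number - aj.seq_number) == 1 \
                and {ai.name, aj.name} <= {"N", "CA", "C", "O", "CB"}:
            continue  # peptide-bond neighbours legitimately sit close
        for a in (ai, aj):
            key = (a.chain_id, a.seq_number)
            counts[key] = counts.get(key, 0) + 1
    return sorted(((c, r, n) for (c, r), n in counts.items()),
                  key=lambda x: -x[2])


def _relax_sidechain_clashes(model: Model, rounds: int = 2) -> Model:
    """Re-pick rotamers of clashing residues until no improvement."""
    for _ in range(rounds):
        clashes = _clashing_residues(model)
        if not clashes:
            break
        for chain_id, resnum, _n in clashes:
            res = model.residue(chain_id, resnum)
            if res is None or res.name in ("GLY", "ALA"):
                continue
            model = mutate_residue(model, chain_id, resnum, res.name)
    return model


# ---------------------------------------------------------------------------
# ensemble perturbation

def _perturb_model(model: Model, sigmas: np.ndarray, rng: np.random.Generator,
                   per_atom: bool = False, model_id: int = 1) -> Model:
    out = model.copy()
    out.model_id = model_id
    for sigma, res in zip(sigmas, out.residues):
        if per_atom:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(0.0, sigma, 3)
        else:
            shift = rng.normal(0.0, sigma, 3)
            for atom in res.atoms:
                atom.coord = atom.coord + shift
    return out


def perturb_ensemble(model: Model, profile: PerturbationProfile) -> StructureEnsemble:
    """Ensemble of independently Gaussian-displaced copies of ``model``.

    Each model displaces every residue rigidly by an isotropic Gaussian
    3-vector with that residue's sigma (per-atom mode via the profile
    flag); the seed makes the output reproducible.
    """
    n_res = len(model.residues)
    if len(profile.sigmas) != n_res:
        raise ValueError(f"profile has {len(profile.sigmas)} sigmas for "
                         f"{n_res} residues")
    rng = np.random.default_rng(profile.seed)
    models = [_perturb_model(model, profile.sigmas, rng, profile.per_atom, k + 1)
              for k in range(profile.n_models)]
    return StructureEnsemble(models, source=f"perturb(seed={profile.seed})")


def translate_chain(model: Model, chain_id: str, vector) -> Model:
    """Copy of the model with one chain rigidly translated."""
    out = model.copy()
    v = np.asarray(vector, float)
    for res in out.residues:
        if res.chain_id == chain_id:
            for atom in res.atoms:
                atom.coord = atom.coord + v
    return out


# ---------------------------------------------------------------------------
# point mutation

def mutate_residue(model: Model, chain_id: str, seq_number: int,
                   new_aa: str) -> Model:
    """Swap one side chain, keeping the backbone fixed.

    The new side chain is built with ideal internal geometry; chi angles
    come from a small built-in table of most-common rotamers plus a chi1
    grid scan, picking the placement with the fewest heavy-atom clashes
    (< 2.4 A) against the rest of the structure.  A same-residue call
    rebuilds the side chain in place (backbone untouched).
    """
    new3 = new_aa.upper() if len(new_aa) == 3 else chem.AA_1TO3.get(new_aa.upper())
    if new3 not in chem.STANDARD_AA:
        raise ValueError(f"unknown amino-acid code {new_aa!r}")
    out = model.copy()
    res = out.residue(chain_id, seq_number)
    if res is None:
        raise ValueError(f"residue {chain_id}{seq_number} not found")
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(f"incomplete backbone at {chain_id}{seq_number}")
    # environment for clash checks: every other residue's heavy atoms
    env = np.array([a.coord for r in out.residues if r is not res
                    for a in r.atoms if not a.is_hydrogen] or
                   np.zeros((0, 3))).reshape(-1, 3)
    candidates = list(chem.ROTAMERS[new3])
    if candidates and candidates[0]:
        base = candidates[0]
        candidates += [(float(chi1),) + tuple(base[1:])
                       for chi1 in range(-180, 180, 30)]
    best, best_clashes = None, None
    for chis in candidates or [()]:
        sc = build_sidechain(new3, n.coord, ca.coord, c.coord, chis or None)
        if sc:
            pts = np.array(list(sc.values()))
            if env.size:
                d = np.linalg.norm(env[None, :, :] - pts[:, None, :], axis=2)
                clashes = int((d < CLASH_DISTANCE).sum())
            else:
                clashes = 0
        else:
            clashes = 0
        if best_clashes is None or clashes < best_clashes:
            best, best_clashes = sc, clashes
        if clashes == 0:
            break
    if best_clashes:
        import logging
        logging.getLogger(__name__).warning(
            "best-effort placement of %s at %s%s leaves %d clash(es)",
            new3, chain_id, seq_number, best_clashes)
    res.name = new3
    backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    res.atoms = backbone
    for name, xyz in (best or {}).items():
        res.add_atom(Atom(name=name, element=chem.infer_element(name), coord=xyz))
    out.reindex()
    return out


# ---------------------------------------------------------------------------
# progressive unfolding

def emulate_unfolding(model: Model, chain_id: str, start_residue: int,
                      n_models: int, seed: int) -> StructureEnsemble:
    """Ensemble with progressively randomized backbone dihedrals.

    Model k randomizes a window growing from ``start_residue`` toward
    the C-terminus (the final model randomizes the whole tail), drawing
    phi/psi from an extended-coil distribution while preserving ideal
    bond geometry; side chains ride rigidly on their backbone frames.
    """
    rng = np.random.default_rng(seed)
    chain = model.chain_residues(chain_id)
    indices = [i for i, r in enumerate(chain) if r.seq_number >= start_residue]
    models = []
    if not indices:
        for k in range(n_models):
            m = model.copy()
            m.model_id = k + 1
            models.append(m)
        return StructureEnsemble(models, source="unfold(noop)")
    idx0 = indices[0]
    w_total = len(chain) - idx0
    for k in range(1, n_models + 1):
        w = math.ceil(k / n_models * w_total)
        models.append(_randomize_window(model, chain_id, idx0, w, rng, k))
    return StructureEnsemble(models, source=f"unfold(seed={seed})")


def _residue_frame(res: Residue) -> np.ndarray:
    return np.array([res.atom("N").coord, res.atom("CA").coord,
                     res.atom("C").coord])


def _randomize_window(model: Model, chain_id: str, idx0: int, w: int,
                      rng: np.random.Generator, model_id: int) -> Model:
    out = model.copy()
    out.model_id = model_id
    chain = out.chain_residues(chain_id)
    orig = [{a.name: a.coord.copy() for a in r.atoms} for r in chain]
    end = idx0 + w
    psi_random: dict[int, float] = {}
    for i in range(idx0, end):
        res = chain[i]
        if i == 0:
            psi_random[i] = float(rng.uniform(100.0, 170.0))
            continue  # no upstream anchor; the first residue keeps its pose
        prev = chain[i - 1]
        if i - 1 in psi_random:
            psi_prev = psi_random[i - 1]
        else:
            # original psi of the last folded residue keeps the junction
            psi_prev = dihedral(orig[i - 1]["N"], orig[i - 1]["CA"],
                                orig[i - 1]["C"], orig[i]["N"])
        new_n = place_atom(prev.atom("N").coord, prev.atom("CA").coord,
                           prev.atom("C").coord, chem.BOND_C_N,
                           chem.ANGLE_CA_C_N, psi_prev)
        new_ca = place_atom(prev.atom("CA").coord, prev.atom("C").coord, new_n,
                            chem.BOND_N_CA, chem.ANGLE_C_N_CA, 180.0)
        phi = float(rng.uniform(-160.0, -60.0))
        psi = float(rng.uniform(100.0, 170.0))
        psi_random[i] = psi
        new_c = place_atom(prev.atom("C").coord, new_n, new_ca,
                           chem.BOND_CA_C, chem.ANGLE_N_CA_C, phi)
        new_o = place_atom(new_n, new_ca, new_c, chem.BOND_C_O,
                           chem.ANGLE_CA_C_O, psi + 180.0)
        old_frame = np.array([orig[i]["N"], orig[i]["CA"], orig[i]["C"]])
        new_frame = np.array([new_n, new_ca, new_c])
        rot, trans, _ = _kabsch(old_frame, new_frame)
        for atom in res.atoms:
            if atom.name == "N":
                atom.coord = new_n
            elif atom.name == "CA":
                atom.coord = new_ca
            elif atom.name == "C":
                atom.coord = new_c
            elif atom.name == "O":
                atom.coord = new_o
            else:
                atom.coord = rot @ orig[i][atom.name] + trans
        if i == end - 1 and end < len(chain):
            # carry the remaining C-terminal segment rigidly on this frame
            for j in range(end, len(chain)):
                for atom in chain[j].atoms:
                    atom.coord = rot @ orig[j][atom.name] + trans
    return out
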