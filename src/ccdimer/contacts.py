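"""Heavy-atom contact enumeration, classification and statistics.

Interface (inter-protomer) and tertiary (intra-protomer) contacts are
counted between non-hydrogen atoms at configurable cutoffs (7 A for
intra-chain packing, 10 A for native-contact retention at mutation
sites).  Contacts are classified into salt bridges, hydrogen bonds,
hydrophobic contacts and generic van der Waals contacts, and replicate
count series are compared with a pooled-variance one-tailed t-test
normalized by the wild-type group mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import t as student_t

from . import chemistry as chem
from .secondary import HBOND_ENERGY_CUTOFF, amide_hydrogen, backbone_hbond_energy, _previous_residue
from .structure import Atom, Model, Selection, StructureEnsemble, select

DEFAULT_CUTOFF_INTRA = 7.0
DEFAULT_CUTOFF_NATIVE = 10.0
SALT_BRIDGE_CUTOFF = 4.0
HBOND_DIST_CUTOFF = 3.5
HBOND_ANGLE_MIN = 120.0
HYDROPHOBIC_CUTOFF = 4.5
VDW_CUTOFF = 4.5
NEIGHBOR_EXCLUSION = 2  # exclude |i-j| < 2 within one chain in intra mode

AtomAddress = tuple[str, int, str]  # (chain, residue number, atom name)


@dataclass
class ContactRecord:
    atom_a: AtomAddress
    atom_b: AtomAddress
    distance: float
    scope: str  # inter_protomer | intra_protomer
    type: str = "unclassified"

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.atom_b < self.atom_a:  # canonical unordered storage
            self.atom_a, self.atom_b = self.atom_b, self.atom_a


@dataclass
class ContactNetwork:
    """Residue-pair edges with atom-pair multiplicity and type tally."""
    cutoff: float
    edges: dict[tuple, dict] = field(default_factory=dict)

    def add(self, record: ContactRecord) -> None:
        ra = (record.atom_a[0], record.atom_a[1])
        rb = (record.atom_b[0], record.atom_b[1])
        key = (ra, rb) if ra <= rb else (rb, ra)
        edge = self.edges.setdefault(key, {"multiplicity": 0, "types": {}})
        edge["multiplicity"] += 1
        edge["types"][record.type] = edge["types"].get(record.type, 0) + 1

    @property
    def residue_pair_count(self) -> int:
        return len(self.edges)

    @property
    def atom_pair_count(self) -> int:
        return sum(e["multiplicity"] for e in self.edges.values())


def _heavy(atoms: Sequence[Atom]) -> list[Atom]:
    return [a for a in atoms if not a.is_hydrogen]


def _address(atom: Atom) -> AtomAddress:
    return (atom.chain_id, atom.seq_number, atom.name)


def atom_contacts(model: Model, group_a: Sequence[Atom], group_b: Sequence[Atom],
                  cutoff: float, neighbor_exclusion: int = NEIGHBOR_EXCLUSION
                  ) -> list[ContactRecord]:
    """All unordered heavy-atom pairs across (or within) the groups at ``cutoff``.

    Passing the same atoms for both groups switches to intra mode, which
    skips pairs within one residue and within ``neighbor_exclusion``
    sequence positions on the same chain so counts measure tertiary
    packing.  Partially overlapping groups are rejected.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = _heavy(group_a)
    b = _heavy(group_b)
    ids_a = {id(x) for x in a}
    ids_b = {id(x) for x in b}
    intra = ids_a == ids_b
    if not intra and ids_a & ids_b:
        raise ValueError("groups overlap; inter-group contacts need disjoint groups")
    records: list[ContactRecord] = []
    if not a or not b:
        return records
    xa = np.array([x.coord for x in a])
    if intra:
        tree = cKDTree(xa)
        for i, j in sorted(tree.query_pairs(cutoff)):
            ai, aj = a[i], a[j]
            if ai.chain_id == aj.chain_id:
                same_res = (ai.seq_number, ai.insertion_code) == \
                           (aj.seq_number, aj.insertion_code)
                if same_res or abs(ai.seq_number - aj.seq_number) < neighbor_exclusion:
                    continue
            d = float(np.linalg.norm(ai.coord - aj.coord))
            records.append(ContactRecord(_address(ai), _address(aj), d,
                                         scope="intra_protomer"))
    else:
        xb = np.array([x.coord for x in b])
        tree = cKDTree(xb)
        for i, hits in enumerate(tree.query_ball_point(xa, cutoff)):
            for j in sorted(hits):
                d = float(np.linalg.norm(xa[i] - xb[j]))
                if d <= cutoff and d > 0:
                    records.append(ContactRecord(_address(a[i]), _address(b[j]), d,
                                                 scope="inter_protomer"))
    return records


def inter_chain_contacts(model: Model, chain_a: str, chain_b: str,
                         cutoff: float = DEFAULT_CUTOFF_INTRA) -> list[ContactRecord]:
    """Heavy-atom contacts across a two-chain interface."""
    if chain_a == chain_b:
        raise ValueError("inter-protomer contacts need two distinct chains")
    ga = select(model, Selection(chains=[chain_a], heavy_only=True))
    gb = select(model, Selection(chains=[chain_b], heavy_only=True))
    return atom_contacts(model, ga, gb, cutoff)


def intra_chain_contacts(model: Model, chain_id: str,
                         cutoff: float = DEFAULT_CUTOFF_INTRA,
                         neighbor_exclusion: int = NEIGHBOR_EXCLUSION
                         ) -> list[ContactRecord]:
    """Tertiary-packing contacts within one chain."""
    g = select(model, Selection(chains=[chain_id], heavy_only=True))
    return atom_contacts(model, g, g, cutoff, neighbor_exclusion)


def residue_contact_count(model: Model, chain_a: str, chain_b: str,
                          cutoff: float = DEFAULT_CUTOFF_INTRA) -> int:
    """Distinct residue pairs across the interface with >=1 heavy-atom contact."""
    records = inter_chain_contacts(model, chain_a, chain_b, cutoff)
    pairs = {((r.atom_a[0], r.atom_a[1]), (r.atom_b[0], r.atom_b[1]))
             for r in records}
    return len(pairs)


def contact_network(model: Model, chain_a: str, chain_b: str,
                    cutoff: float = DEFAULT_CUTOFF_INTRA) -> ContactNetwork:
    net = ContactNetwork(cutoff=cutoff)
    for rec in inter_chain_contacts(model, chain_a, chain_b, cutoff):
        rec.type = classify_contact(rec, model)
        net.add(rec)
    return net


# ---------------------------------------------------------------------------
# classification

def _resolve(model: Model, addr: AtomAddress) -> Atom:
    atom = model.atom(addr[0], addr[1], addr[2])
    if atom is None:
        raise ValueError(f"cannot resolve atom {addr}")
    return atom


def _is_terminal(model: Model, atom: Atom, which: str) -> bool:
    chain = model.chain_residues(atom.chain_id)
    if not chain:
        return False
    res = chain[0] if which == "first" else chain[-1]
    return (res.seq_number, res.insertion_code) == (atom.seq_number, atom.insertion_code)


def _is_basic(model: Model, atom: Atom) -> bool:
    if atom.name in chem.BASIC_ATOMS.get(atom.res_name, ()):
        return True
    return atom.name == "N" and _is_terminal(model, atom, "first")


def _is_acidic(model: Model, atom: Atom) -> bool:
    if atom.name in chem.ACIDIC_ATOMS.get(atom.res_name, ()):
        return True
    if not _is_terminal(model, atom, "last"):
        return False
    if atom.name == "OXT":
        return True
    last = model.chain_residues(atom.chain_id)[-1]
    has_oxt = any(a.name == "OXT" for a in last.atoms)
    return atom.name == "O" and not has_oxt


def _donor_role(model: Model, atom: Atom) -> tuple[bool, np.ndarray | None]:
    """(is_donor, approximate H position or None)."""
    res = model.residue(atom.chain_id, atom.seq_number, atom.insertion_code)
    if res is None:
        return False, None
    if atom.name == "N":
        if res.name == "PRO":
            return False, None
        h = amide_hydrogen(res, _previous_residue(model, res))
        return True, h
    ant_name = chem.SIDECHAIN_DONORS.get(res.name, {}).get(atom.name)
    if ant_name is None:
        return False, None
    for name in [n for n in (f"H{atom.name[1:]}",) if n]:
        h = res.atom(name)
        if h is not None:
            return True, h.coord
    return True, None  # donor with unknown proton position


def _acceptor_role(model: Model, atom: Atom) -> bool:
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in chem.SIDECHAIN_ACCEPTORS.get(atom.res_name, ())


def _hbond_geometry_ok(model: Model, donor: Atom, acceptor: Atom,
                       h_pos: np.ndarray | None) -> bool:
    if h_pos is not None:
        v1 = donor.coord - h_pos
        v2 = acceptor.coord - h_pos
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        angle = math.degrees(math.acos(np.clip(c, -1.0, 1.0)))
        return angle >= HBOND_ANGLE_MIN
    # no proton position (rotatable side-chain donor): require the
    # acceptor to lie on the outward side of the donor's antecedent
    res = model.residue(donor.chain_id, donor.seq_number, donor.insertion_code)
    ant_name = chem.SIDECHAIN_DONORS.get(res.name, {}).get(donor.name)
    ant = res.atom(ant_name) if ant_name else None
    if ant is None:
        return True
    v1 = ant.coord - donor.coord
    v2 = acceptor.coord - donor.coord
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    angle = math.degrees(math.acos(np.clip(c, -1.0, 1.0)))
    return angle >= 90.0


def classify_contact(record: ContactRecord, model: Model) -> str:
    """Assign a contact type: salt bridge > hydrogen bond > hydrophobic > vdW."""
    a = _resolve(model, record.atom_a)
    b = _resolve(model, record.atom_b)
    d = record.distance
    if d <= SALT_BRIDGE_CUTOFF:
        if (_is_basic(model, a) and _is_acidic(model, b)) or \
           (_is_basic(model, b) and _is_acidic(model, a)):
            return "salt_bridge"
    if d <= HBOND_DIST_CUTOFF and a.element in "NO" and b.element in "NO":
        for donor, acceptor in ((a, b), (b, a)):
            is_donor, h = _donor_role(model, donor)
            if is_donor and _acceptor_role(model, acceptor) and \
                    _hbond_geometry_ok(model, donor, acceptor, h):
                return "hydrogen_bond"
    if d <= HYDROPHOBIC_CUTOFF:
        if a.name in chem.APOLAR_ATOMS.get(a.res_name, ()) and \
           b.name in chem.APOLAR_ATOMS.get(b.res_name, ()):
            return "hydrophobic"
    if d <= VDW_CUTOFF:
        return "van_der_waals"
    return "unclassified"


# ---------------------------------------------------------------------------
# backbone hydrogen bonds, native contacts, occupancy

def backbone_hbond_count(model: Model, selection: Selection | None = None) -> int:
    """Count of i -> i+n (n >= 2) backbone N-H...O=C bonds (energy criterion)."""
    if selection is None:
        residues = list(model.residues)
    else:
        atoms = select(model, selection)
        keys = {(a.chain_id, a.seq_number, a.insertion_code) for a in atoms}
        residues = [r for r in model.residues if r.key in keys]
    count = 0
    coords = {}
    for r in residues:
        ca = r.atom("CA")
        coords[r.key] = ca.coord if ca is not None else None
    for donor in residues:
        for acceptor in residues:
            if donor.chain_id == acceptor.chain_id and \
                    abs(donor.seq_number - acceptor.seq_number) < 2:
                continue
            cd, cacc = coords[donor.key], coords[acceptor.key]
            if cd is None or cacc is None or np.linalg.norm(cd - cacc) > 9.0:
                continue
            e = backbone_hbond_energy(donor, acceptor, model)
            if not math.isnan(e) and e < HBOND_ENERGY_CUTOFF:
                count += 1
    return count


def native_contact_fraction(ensemble: StructureEnsemble, reference_model: Model,
                            selection_a: Selection, selection_b: Selection,
                            cutoff: float = DEFAULT_CUTOFF_NATIVE
                            ) -> tuple[list[float], float]:
    """Retention of reference contacts across the ensemble.

    The native set is every heavy-atom pair between the two selections
    within ``cutoff`` in the reference; each model's fraction is the
    share of those pairs still within ``cutoff``.
    """
    ga = select(reference_model, selection_a)
    gb = select(reference_model, selection_b)
    native = atom_contacts(reference_model, ga, gb, cutoff)
    if not native:
        raise ValueError("empty native contact set")
    pairs = [(r.atom_a, r.atom_b) for r in native]
    fractions: list[float] = []
    for model in ensemble.models:
        kept = 0
        for pa, pb in pairs:
            atom_a = model.atom(pa[0], pa[1], pa[2])
            atom_b = model.atom(pb[0], pb[1], pb[2])
            if atom_a is None or atom_b is None:
                continue
            if np.linalg.norm(atom_a.coord - atom_b.coord) <= cutoff:
                kept += 1
        fractions.append(kept / len(pairs))
    return fractions, float(np.mean(fractions))


def salt_bridge_occupancy(ensemble: StructureEnsemble,
                          pair: tuple[tuple[str, int], tuple[str, int]]) -> float:
    """Fraction of models in which the residue pair forms a salt bridge."""
    (ca_id, ra), (cb_id, rb) = pair
    ref = ensemble.first
    res_a = ref.residue(ca_id, ra)
    res_b = ref.residue(cb_id, rb)
    if res_a is None or res_b is None:
        raise ValueError(f"residue pair {pair} not found")
    names = {res_a.name, res_b.name}
    if not (names & set(chem.BASIC_ATOMS)) or not (names & set(chem.ACIDIC_ATOMS)):
        raise ValueError(f"{res_a.name}/{res_b.name} is not a basic/acidic pair")
    basic_res, acidic_res = (res_a, res_b) if res_a.name in chem.BASIC_ATOMS \
        else (res_b, res_a)
    basic_names = chem.BASIC_ATOMS[basic_res.name]
    acidic_names = chem.ACIDIC_ATOMS[acidic_res.name]
    bridged = 0
    for model in ensemble.models:
        ba = [model.atom(basic_res.chain_id, basic_res.seq_number, n)
              for n in basic_names]
        ac = [model.atom(acidic_res.chain_id, acidic_res.seq_number, n)
              for n in acidic_names]
        dmin = min((np.linalg.norm(x.coord - y.coord)
                    for x in ba for y in ac if x is not None and y is not None),
                   default=math.inf)
        if dmin <= SALT_BRIDGE_CUTOFF:
            bridged += 1
    return bridged / len(ensemble.models)


# ---------------------------------------------------------------------------
# replicate statistics

@dataclass
class ContactStats:
    """Wild-type-normalized comparison of two replicate groups."""
    wt_means: tuple
    mut_means: tuple
    wt_mean: float
    mut_mean: float
    wt_sd: float
    mut_sd: float
    normalized: float
    t: float
    p: float
    df: int


def contact_stats(replicate_counts_wt: Sequence[float],
                  replicate_counts_mut: Sequence[float]) -> ContactStats:
    """Pooled-variance one-tailed Student t comparison, wt-normalized.

    The p-value is one-tailed in the direction of the observed
    difference; identical groups give t = 0 and p = 0.5.
    """
    wt = np.asarray(replicate_counts_wt, float)
    mut = np.asarray(replicate_counts_mut, float)
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need at least two replicates per group")
    m1, m2 = wt.mean(), mut.mean()
    if m1 == 0:
        raise ZeroDivisionError("wild-type mean is zero; cannot normalize")
    s1, s2 = wt.std(ddof=1), mut.std(ddof=1)
    n1, n2 = len(wt), len(mut)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    denom = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if denom == 0:
        t_stat = 0.0 if m1 == m2 else math.copysign(math.inf, m2 - m1)
        p = 0.5 if m1 == m2 else 0.0
    else:
        t_stat = (m2 - m1) / denom
        p = float(student_t.sf(abs(t_stat), df))
    return ContactStats(wt_means=tuple(wt), mut_means=tuple(mut),
                        wt_mean=float(m1), mut_mean=float(m2),
                        wt_sd=float(s1), mut_sd=float(s2),
                        normalized=float(m2 / m1), t=float(t_stat), p=p, df=df)
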