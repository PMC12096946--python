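"""Multi-model protein structure data model and PDB/mmCIF I/O.

An ensemble is an ordered list of models sharing one topology (same
chains, residues and atom names).  NMR ensembles, MD frame dumps written
as multi-MODEL PDB files, and generated synthetic ensembles are all
represented the same way.  Author chain IDs and residue numbers are kept
verbatim; waters and hetero residues are dropped at load.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .chemistry import STANDARD_AA, infer_element

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class TopologyError(ValueError):
    """Raised when models of one ensemble disagree in topology."""


class SelectionError(ValueError):
    """Raised when a selection references unknown chains/atoms."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    # back-references filled by the owning residue
    chain_id: str = ""
    seq_number: int = 0
    insertion_code: str = ""
    res_name: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            self.element = infer_element(self.name)


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self):
        for a in self.atoms:
            self._adopt(a)

    def _adopt(self, atom: Atom) -> None:
        atom.chain_id = self.chain_id
        atom.seq_number = self.seq_number
        atom.insertion_code = self.insertion_code
        atom.res_name = self.name

    def add_atom(self, atom: Atom) -> None:
        self._adopt(atom)
        self.atoms.append(atom)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


class Model:
    """One model/frame: residues grouped by chain, with O(1) atom lookup."""

    def __init__(self, model_id: int, residues: Sequence[Residue]):
        self.model_id = model_id
        self.residues: list[Residue] = list(residues)
        self._index: dict[tuple, Residue] = {}
        self.reindex()

    def reindex(self) -> None:
        self._index = {}
        for res in self.residues:
            if res.key in self._index:
                raise TopologyError(f"duplicate residue {res.key}")
            self._index[res.key] = res

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for res in self.residues:
            seen.setdefault(res.chain_id, None)
        return list(seen)

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def residue(self, chain_id: str, seq_number: int,
                insertion_code: str = "") -> Residue | None:
        return self._index.get((chain_id, seq_number, insertion_code))

    def atom(self, chain_id: str, seq_number: int, atom_name: str) -> Atom | None:
        res = self.residue(chain_id, seq_number)
        return res.atom(atom_name) if res is not None else None

    def atoms(self) -> Iterable[Atom]:
        for res in self.residues:
            yield from res.atoms

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms() if not a.is_hydrogen)

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Model":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for atom in out.atoms():
            atom.coord = R @ atom.coord + t
        return out

    def topology_signature(self) -> list[tuple]:
        return [(r.chain_id, r.seq_number, r.insertion_code, r.name,
                 tuple(a.name for a in r.atoms)) for r in self.residues]


class StructureEnsemble:
    """Ordered models sharing one topology."""

    def __init__(self, models: Sequence[Model], source: str = "",
                 frame_spacing: float | None = None):
        if len(models) < 1:
            raise ValueError("an ensemble needs at least one model")
        self.models: list[Model] = list(models)
        self.source = source
        self.frame_spacing = frame_spacing
        self._check_topology()

    def _check_topology(self) -> None:
        ref = self.models[0].topology_signature()
        for m in self.models[1:]:
            sig = m.topology_signature()
            if sig != ref:
                for a, b in zip(ref, sig):
                    if a != b:
                        raise TopologyError(
                            f"model {m.model_id} differs from model "
                            f"{self.models[0].model_id} at residue "
                            f"{b[:4]} (expected {a[:4]} with atoms {a[4]})")
                raise TopologyError(
                    f"model {m.model_id} has {len(sig)} residues, "
                    f"expected {len(ref)}")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    @property
    def first(self) -> Model:
        return self.models[0]

    def copy(self) -> "StructureEnsemble":
        return StructureEnsemble([m.copy() for m in self.models],
                                 source=self.source,
                                 frame_spacing=self.frame_spacing)


@dataclass
class Selection:
    """Declarative atom selection.

    chains: chain IDs to include (None = all chains)
    residue_ranges: list of (start, end) inclusive author-numbering ranges
    atom_names: atom names to include (None = all)
    heavy_only: drop hydrogens
    """
    chains: Sequence[str] | None = None
    residue_ranges: Sequence[tuple[int, int]] | None = None
    atom_names: Sequence[str] | None = None
    heavy_only: bool = False


def select(model: Model, spec: Selection) -> list[Atom]:
    """Atoms matching ``spec`` in deterministic (chain, residue, file) order."""
    if spec.chains is not None:
        known = set(model.chains)
        for c in spec.chains:
            if c not in known:
                raise SelectionError(f"unknown chain {c!r}; model has {sorted(known)}")
    chains = set(spec.chains) if spec.chains is not None else None
    names = set(spec.atom_names) if spec.atom_names is not None else None
    out: list[Atom] = []
    for res in model.residues:
        if chains is not None and res.chain_id not in chains:
            continue
        if spec.residue_ranges is not None:
            if not any(lo <= res.seq_number <= hi for lo, hi in spec.residue_ranges):
                continue
        for atom in res.atoms:
            if spec.heavy_only and atom.is_hydrogen:
                continue
            if names is not None and atom.name not in names:
                continue
            out.append(atom)
    return out


def coords(atoms: Sequence[Atom]) -> np.ndarray:
    """(n, 3) coordinate array for an atom list."""
    if not atoms:
        return np.zeros((0, 3))
    return np.array([a.coord for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# I/O via gemmi

def _convert_gemmi_residue(chain_id: str, gres: "gemmi.Residue") -> Residue | None:
    name = gres.name.strip()
    if name == "HOH" or name not in STANDARD_AA:
        logger.debug("dropping non-protein residue %s %s%s",
                     name, chain_id, gres.seqid.num)
        return None
    # altlocs: keep highest occupancy per atom name, ties -> altloc 'A'/''
    chosen: dict[str, "gemmi.Atom"] = {}
    for ga in gres:
        prev = chosen.get(ga.name)
        if prev is None:
            chosen[ga.name] = ga
            continue
        if (ga.occ, -ord(ga.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
            chosen[ga.name] = ga
    res = Residue(chain_id=chain_id, seq_number=gres.seqid.num, name=name,
                  insertion_code=(gres.seqid.icode or "").strip())
    for ga in gres:  # keep file order
        if chosen.get(ga.name) is not ga:
            continue
        el = ga.element.name if ga.element and ga.element.name != "X" else ""
        if not el:
            el = infer_element(ga.name)
            logger.debug("inferred element %s for atom %s", el, ga.name)
        res.add_atom(Atom(name=ga.name, element=el,
                          coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                          occupancy=ga.occ, bfactor=ga.b_iso))
    return res


def read_structure(path: str | Path, format: str = "auto") -> StructureEnsemble:
    """Read a PDB or mmCIF file; every MODEL block becomes one model.

    Hydrogens are retained (flagged through ``Atom.is_hydrogen``); waters
    and hetero residues are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    models: list[Model] = []
    for i, gmodel in enumerate(st):
        residues: list[Residue] = []
        for gchain in gmodel:
            for gres in gchain:
                res = _convert_gemmi_residue(gchain.name, gres)
                if res is not None:
                    residues.append(res)
        num = getattr(gmodel, "num", None)
        if num is None:
            try:
                num = int(getattr(gmodel, "name", i + 1))
            except (ValueError, TypeError):
                num = i + 1
        models.append(Model(model_id=num, residues=residues))
    if not models or not models[0].residues:
        raise ParseError(f"{path}: no protein residues found")
    return StructureEnsemble(models, source=str(path))


def read_frames(paths: Sequence[str | Path]) -> StructureEnsemble:
    """Treat a list of single-model files (e.g. per-frame PDBs) as one ensemble."""
    models: list[Model] = []
    for i, p in enumerate(sorted(str(x) for x in paths)):
        ens = read_structure(p)
        for m in ens.models:
            m.model_id = len(models) + 1
            models.append(m)
    return StructureEnsemble(models, source=";".join(sorted(str(p) for p in paths)))


def strip_hydrogens(ensemble: StructureEnsemble) -> StructureEnsemble:
    """New ensemble with all element-H/D atoms removed; input untouched."""
    out = ensemble.copy()
    for model in out.models:
        for res in model.residues:
            res.atoms = [a for a in res.atoms if not a.is_hydrogen]
    return out


def write_structure(ensemble: StructureEnsemble, path: str | Path,
                    format: str = "pdb") -> Path:
    """Write the ensemble as a (multi-MODEL) PDB file."""
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    st = gemmi.Structure()
    st.name = "ccdimer"
    ids = [m.model_id for m in ensemble.models]
    if len(set(ids)) != len(ids):
        ids = list(range(1, len(ids) + 1))
    for model, mid in zip(ensemble.models, ids):
        gmodel = gemmi.Model(mid)
        by_chain: dict[str, gemmi.Chain] = {}
        for res in model.residues:
            gchain = by_chain.get(res.chain_id)
            if gchain is None:
                gchain = gemmi.Chain(res.chain_id)
                by_chain[res.chain_id] = gchain
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                ga.b_iso = atom.bfactor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        for gchain in by_chain.values():
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    path = Path(path)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path
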