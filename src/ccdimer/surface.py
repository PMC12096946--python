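"""Solvent-accessible surface area, buried surface, and charge profiles.

SASA uses the Shrake-Rupley sphere-point method with a deterministic
golden-spiral point set (no RNG), Bondi van der Waals radii, and a
1.4 A water probe.  Buried surface area follows the both-sides
convention BSA = SASA(A) + SASA(B) - SASA(AB), with no division by two,
over heavy atoms only -- stated prominently because published interface
areas are convention-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import FORMAL_CHARGE, VDW_RADII
from .geometry import HelixAxis
from .structure import Atom, Model, Selection, select

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


@dataclass
class SasaResult:
    per_atom: dict[tuple, float]     # (chain, resnum, atom name) -> A^2
    probe_radius: float
    n_sphere_points: int
    per_residue: dict[tuple, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.per_residue:
            for (chain, resnum, _name), area in self.per_atom.items():
                key = (chain, resnum)
                self.per_residue[key] = self.per_residue.get(key, 0.0) + area

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def sasa(model: Model, selection: Selection | None = None,
         probe_radius: float = PROBE_RADIUS,
         n_points: int = N_SPHERE_POINTS) -> SasaResult:
    """Shrake-Rupley SASA of the selected atoms, occluded only by each other.

    Hydrogens are excluded; pass a selection covering one chain to get
    that chain "alone" as needed for buried-surface bookkeeping.
    """
    if selection is None:
        selection = Selection(heavy_only=True)
    atoms = [a for a in select(model, selection) if not a.is_hydrogen]
    if not atoms:
        raise ValueError("empty selection")
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = VDW_RADII.get(a.element)
        if r is None:
            raise ValueError(f"no van der Waals radius for element {a.element!r}")
        radii[i] = r + probe_radius
    xyz = np.array([a.coord for a in atoms])
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    per_atom: dict[tuple, float] = {}
    for i, a in enumerate(atoms):
        pts = xyz[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        frac = accessible.mean()
        per_atom[(a.chain_id, a.seq_number, a.name)] = \
            float(4.0 * np.pi * radii[i] ** 2 * frac)
    return SasaResult(per_atom=per_atom, probe_radius=probe_radius,
                      n_sphere_points=n_points)


def buried_surface_area(model: Model, chain_a: str, chain_b: str,
                        probe_radius: float = PROBE_RADIUS,
                        n_points: int = N_SPHERE_POINTS) -> float:
    """BSA = SASA(A alone) + SASA(B alone) - SASA(complex), both sides."""
    chains = set(model.chains)
    for c in (chain_a, chain_b):
        if c not in chains:
            raise ValueError(f"chain {c!r} not in model (has {sorted(chains)})")
    kw = dict(probe_radius=probe_radius, n_points=n_points)
    sa = sasa(model, Selection(chains=[chain_a], heavy_only=True), **kw)
    sb = sasa(model, Selection(chains=[chain_b], heavy_only=True), **kw)
    sab = sasa(model, Selection(chains=[chain_a, chain_b], heavy_only=True), **kw)
    return sa.total + sb.total - sab.total


def ensemble_bsa(ensemble, chain_a: str, chain_b: str, **kw) -> dict:
    """Per-model BSA summary: model-1 value, mean, and s.d. across models."""
    values = [buried_surface_area(m, chain_a, chain_b, **kw)
              for m in ensemble.models]
    return {"bsa_model1": values[0],
            "bsa_mean": float(np.mean(values)),
            "bsa_sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0}


@dataclass
class ChargeProfile:
    bin_centers: np.ndarray    # A along the helix axis
    bin_charges: np.ndarray    # summed formal charge per bin
    net_charge: int

    def __post_init__(self):
        assert int(round(self.bin_charges.sum())) == self.net_charge


def charge_profile(model: Model, chain_id: str, axis: HelixAxis,
                   bin_width: float = 5.0,
                   include_termini: bool = False) -> ChargeProfile:
    """Formal side-chain charges (K/R +1, D/E -1, H 0) binned by the CA
    projection onto the helix axis.

    Terminal backbone charges are excluded by default (the constructs
    analyzed here are internal fragments of larger proteins).
    """
    residues = model.chain_residues(chain_id)
    if not residues:
        raise ValueError(f"no residues in chain {chain_id!r}")
    entries: list[tuple[float, int]] = []
    for i, res in enumerate(residues):
        ca = res.atom("CA")
        if ca is None:
            continue
        q = FORMAL_CHARGE.get(res.name, 0)
        if include_termini:
            if i == 0:
                q += 1
            if i == len(residues) - 1:
                q -= 1
        if q != 0:
            entries.append((axis.project(ca.coord), q))
    if entries:
        positions = np.array([e[0] for e in entries])
        lo = np.floor(positions.min() / bin_width) * bin_width
        hi = np.ceil(positions.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        charges = np.zeros(len(edges) - 1)
        for pos, q in entries:
            idx = min(int((pos - lo) // bin_width), len(charges) - 1)
            charges[idx] += q
        centers = (edges[:-1] + edges[1:]) / 2
    else:
        centers = np.array([0.0])
        charges = np.array([0.0])
    net = int(round(charges.sum()))
    return ChargeProfile(bin_centers=centers, bin_charges=charges, net_charge=net)
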