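"""Helix-axis and aromatic-ring geometry.

Axis fitting uses the classic local-helical-center construction: each
center is the mean of four consecutive CA atoms, and the axis is the
principal direction of those centers oriented N -> C.  Crossing angles
between two axes decide parallel vs antiparallel topology; for
antiparallel coiled coils the reported packing angle is folded to
min(theta, 180 - theta) so it is comparable across conventions.

Aromatic ring pairs are characterized by the interplanar (normal-normal)
angle, the CZ-CZ distance (Tyr/Phe), and the centroid separation, and
classified as parallel-stacked or edge-to-face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import chemistry as chem
from .structure import Model, Residue, StructureEnsemble

PARALLEL_MAX_ANGLE = 30.0     # deg, interplanar angle below -> parallel
EDGE_TO_FACE_MIN_ANGLE = 60.0  # deg, above -> edge-to-face (T-shaped)
STACKING_MAX_CENTROID = 7.5   # A, centroid gate for either class
MET_AROMATIC_CUTOFF = 6.0     # A, Met SD to ring centroid
CHPI_MAX_DIST = 4.5           # A, aliphatic C to ring centroid
CHPI_MAX_NORMAL_ANGLE = 40.0  # deg, off the ring normal


class FitError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass
class HelixAxis:
    anchor: np.ndarray        # point on the axis
    direction: np.ndarray     # unit vector, oriented N -> C
    residue_range: tuple[int, int]
    fit_rmsd: float

    def project(self, point: np.ndarray) -> float:
        """Signed coordinate of a point along the axis."""
        return float(np.dot(np.asarray(point) - self.anchor, self.direction))


def fit_helix_axis(model: Model, chain_id: str,
                   residue_range: tuple[int, int] | None = None) -> HelixAxis:
    """Least-squares axis through the local helical centers of a CA trace."""
    residues = model.chain_residues(chain_id)
    if residue_range is not None:
        lo, hi = residue_range
        residues = [r for r in residues if lo <= r.seq_number <= hi]
    cas = [r.atom("CA") for r in residues]
    if any(a is None for a in cas) or len(cas) < 7:
        raise FitError(f"need >=7 consecutive CA atoms in chain {chain_id}")
    ca = np.array([a.coord for a in cas])
    gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if np.any(gaps > 4.5):
        raise FitError(f"chain break within residue range on chain {chain_id}")
    centers = np.array([ca[i:i + 4].mean(axis=0) for i in range(len(ca) - 3)])
    anchor = centers.mean(axis=0)
    _, _, vt = np.linalg.svd(centers - anchor)
    direction = vt[0]
    if np.dot(direction, centers[-1] - centers[0]) < 0:
        direction = -direction
    perp = (centers - anchor) - np.outer((centers - anchor) @ direction, direction)
    fit_rmsd = float(np.sqrt((perp ** 2).sum(axis=1).mean()))
    rng = (residues[0].seq_number, residues[-1].seq_number)
    return HelixAxis(anchor=anchor, direction=direction / np.linalg.norm(direction),
                     residue_range=rng, fit_rmsd=fit_rmsd)


@dataclass
class CrossingAngle:
    theta: float         # deg in [0, 180] between N->C directions
    packing_angle: float  # min(theta, 180 - theta)
    orientation: str     # parallel | antiparallel


def crossing_angle(axis_a: HelixAxis, axis_b: HelixAxis) -> CrossingAngle:
    c = float(np.clip(np.dot(axis_a.direction, axis_b.direction), -1.0, 1.0))
    theta = math.degrees(math.acos(c))
    orientation = "antiparallel" if theta > 90.0 else "parallel"
    return CrossingAngle(theta=theta, packing_angle=min(theta, 180.0 - theta),
                         orientation=orientation)


# ---------------------------------------------------------------------------
# aromatic ring geometry

@dataclass
class RingGeometry:
    interplanar_angle: float       # deg, folded into [0, 90]
    cz_cz_distance: float | None   # A, Tyr/Phe only
    centroid_distance: float
    stacking_class: str            # parallel | edge_to_face | none


def _ring_atoms(residue: Residue) -> np.ndarray:
    names = chem.RING_ATOMS.get(residue.name)
    if names is None:
        raise GeometryError(f"{residue.name} is not aromatic")
    coords = []
    for n in names:
        atom = residue.atom(n)
        if atom is None:
            raise GeometryError(
                f"incomplete ring: {residue.name} {residue.chain_id}"
                f"{residue.seq_number} lacks {n}")
        coords.append(atom.coord)
    return np.array(coords)


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def ring_geometry(model: Model, res_a: tuple[str, int], res_b: tuple[str, int],
                  parallel_max: float = PARALLEL_MAX_ANGLE,
                  edge_min: float = EDGE_TO_FACE_MIN_ANGLE,
                  centroid_gate: float = STACKING_MAX_CENTROID) -> RingGeometry:
    """Interplanar angle, CZ-CZ distance, and stacking class for a ring pair."""
    ra = model.residue(*res_a)
    rb = model.residue(*res_b)
    if ra is None or rb is None:
        raise GeometryError(f"residue {res_a} or {res_b} not found")
    ca = _ring_atoms(ra)
    cb = _ring_atoms(rb)
    na, nb = _plane_normal(ca), _plane_normal(cb)
    cosang = abs(float(np.clip(np.dot(na, nb), -1.0, 1.0)))
    angle = math.degrees(math.acos(cosang))  # folded into [0, 90]
    centroid_distance = float(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0)))
    cz_cz = None
    if ra.name in ("TYR", "PHE") and rb.name in ("TYR", "PHE"):
        za, zb = ra.atom("CZ"), rb.atom("CZ")
        if za is not None and zb is not None:
            cz_cz = float(np.linalg.norm(za.coord - zb.coord))
    if centroid_distance <= centroid_gate and angle < parallel_max:
        cls = "parallel"
    elif centroid_distance <= centroid_gate and angle > edge_min:
        cls = "edge_to_face"
    else:
        cls = "none"
    return RingGeometry(interplanar_angle=angle, cz_cz_distance=cz_cz,
                        centroid_distance=centroid_distance, stacking_class=cls)


def ring_class_series(ensemble: StructureEnsemble, res_a: tuple[str, int],
                      res_b: tuple[str, int], **kwargs
                      ) -> tuple[list[RingGeometry], dict[str, float]]:
    """Per-model ring geometry plus the fraction of models in each class."""
    series = [ring_geometry(m, res_a, res_b, **kwargs) for m in ensemble.models]
    n = len(series)
    fractions = {cls: sum(1 for g in series if g.stacking_class == cls) / n
                 for cls in ("parallel", "edge_to_face", "none")}
    return series, fractions


# ---------------------------------------------------------------------------
# Met-aromatic and CH-pi interactions

@dataclass
class RingInteraction:
    kind: str                 # met_aromatic | ch_pi
    donor: tuple[str, int, str]   # (chain, residue, atom)
    ring_residue: tuple[str, int]
    distance: float           # to ring centroid
    normal_angle: float | None


def met_aromatic_and_chpi(model: Model,
                          met_cutoff: float = MET_AROMATIC_CUTOFF,
                          chpi_dist: float = CHPI_MAX_DIST,
                          chpi_angle: float = CHPI_MAX_NORMAL_ANGLE
                          ) -> list[RingInteraction]:
    """Met SD over ring faces and aliphatic C-H groups over ring faces.

    Met-aromatic: SD within ``met_cutoff`` of a ring centroid.  CH-pi: an
    aliphatic side-chain carbon within ``chpi_dist`` of the centroid and
    within ``chpi_angle`` of the ring normal (i.e. over the face, not the
    edge).  Interactions within one residue are skipped.
    """
    rings = []
    for res in model.residues:
        if res.name in chem.AROMATIC_RESIDUES:
            try:
                coords = _ring_atoms(res)
            except GeometryError:
                continue
            rings.append((res, coords.mean(axis=0), _plane_normal(coords)))
    out: list[RingInteraction] = []
    for res in model.residues:
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            for ring_res, centroid, normal in rings:
                if res is ring_res:
                    continue
                v = atom.coord - centroid
                d = float(np.linalg.norm(v))
                if atom.res_name == "MET" and atom.name == "SD" and d <= met_cutoff:
                    out.append(RingInteraction(
                        "met_aromatic", (atom.chain_id, atom.seq_number, atom.name),
                        (ring_res.chain_id, ring_res.seq_number), d, None))
                    continue
                if atom.element != "C" or \
                        atom.name not in chem.APOLAR_ATOMS.get(atom.res_name, ()) or \
                        atom.name == "CB" and atom.res_name in chem.AROMATIC_RESIDUES:
                    continue
                if d <= chpi_dist and d > 1e-6:
                    cosang = abs(float(np.dot(v / d, normal)))
                    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                    if ang <= chpi_angle:
                        out.append(RingInteraction(
                            "ch_pi", (atom.chain_id, atom.seq_number, atom.name),
                            (ring_res.chain_id, ring_res.seq_number), d, ang))
    return out
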