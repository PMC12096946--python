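"""Helix axes, crossing angles, ring stacking, Met-aromatic and CH-pi."""

import math

import numpy as np
import pytest

from conftest import random_rotation
from ccdimer.geometry import (CrossingAngle, FitError, GeometryError, HelixAxis,
                              crossing_angle, fit_helix_axis,
                              met_aromatic_and_chpi, ring_class_series,
                              ring_geometry)
from ccdimer.structure import Atom, Model, Residue, StructureEnsemble


def test_axis_of_ideal_helix(helix30):
    axis = fit_helix_axis(helix30, "A")
    assert axis.fit_rmsd < 0.3
    ca = np.array([r.atom("CA").coord for r in helix30.residues])
    chord = ca[-1] - ca[0]
    chord /= np.linalg.norm(chord)
    assert abs(np.dot(axis.direction, chord)) > 0.999
    assert np.dot(axis.direction, chord) > 0  # oriented N -> C


def test_axis_requires_seven_residues(helix30):
    with pytest.raises(FitError):
        fit_helix_axis(helix30, "A", (1, 5))


def test_axis_equivariant_under_rigid_motion(helix30):
    rng = np.random.default_rng(2)
    rot = random_rotation(rng)
    trans = np.array([3.0, -8.0, 12.0])
    moved = helix30.transform(rot, trans)
    a0 = fit_helix_axis(helix30, "A")
    a1 = fit_helix_axis(moved, "A")
    assert np.allclose(a1.direction, rot @ a0.direction, atol=1e-9)
    assert a1.fit_rmsd == pytest.approx(a0.fit_rmsd, abs=1e-9)


def test_reversed_residue_order_flips_direction(helix30):
    rev = Model(1, [r for r in reversed(helix30.copy().residues)])
    a0 = fit_helix_axis(helix30, "A")
    a1 = fit_helix_axis(rev, "A")
    assert np.dot(a0.direction, a1.direction) < -0.999


def test_crossing_angle_conventions():
    a = HelixAxis(np.zeros(3), np.array([0, 0, 1.0]), (1, 10), 0.0)
    same = crossing_angle(a, a)
    assert same.theta == pytest.approx(0.0) and same.orientation == "parallel"
    b = HelixAxis(np.zeros(3), np.array([0, 0, -1.0]), (1, 10), 0.0)
    anti = crossing_angle(a, b)
    assert anti.theta == pytest.approx(180.0)
    assert anti.orientation == "antiparallel"


def test_crossing_angle_complement_identity(palb2_homodimer):
    a = fit_helix_axis(palb2_homodimer, "A", (11, 39))
    b = fit_helix_axis(palb2_homodimer, "B", (11, 39))
    rev_b = HelixAxis(b.anchor, -b.direction, b.residue_range, b.fit_rmsd)
    assert crossing_angle(a, b).theta + crossing_angle(a, rev_b).theta == \
        pytest.approx(180.0, abs=1e-9)


def test_homodimer_is_antiparallel_with_constructed_packing_angle(palb2_homodimer):
    a = fit_helix_axis(palb2_homodimer, "A", (11, 39))
    b = fit_helix_axis(palb2_homodimer, "B", (11, 39))
    cr = crossing_angle(a, b)
    assert cr.orientation == "antiparallel"
    # construction: both axes tilt by atan(2*pi*R/P) off the supercoil axis
    expected = 2 * math.degrees(math.atan(2 * math.pi * 4.9 / 145.0))
    assert abs(cr.packing_angle - expected) <= 5.0


# ---------------------------------------------------------------------------
# ring geometry

def _hexagon(center, normal, radius=1.39):
    normal = np.asarray(normal, float)
    normal /= np.linalg.norm(normal)
    helper = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    pts = []
    for k in range(6):
        ang = k * math.pi / 3
        pts.append(np.asarray(center) + radius * (math.cos(ang) * u + math.sin(ang) * v))
    return pts


def _phe(chain, num, center, normal):
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")  # hexagon walk order
    pts = _hexagon(center, normal)
    return Residue(chain, num, "PHE",
                   [Atom(n, "C", p) for n, p in zip(names, pts)])


def test_stacked_rings_are_parallel():
    m = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]),
                  _phe("B", 1, [0, 0, 3.5], [0, 0, 1])])
    g = ring_geometry(m, ("A", 1), ("B", 1))
    assert g.interplanar_angle < 5.0
    assert g.stacking_class == "parallel"
    assert g.centroid_distance == pytest.approx(3.5, abs=1e-6)
    assert g.cz_cz_distance is not None


def test_t_shaped_rings_are_edge_to_face():
    m = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]),
                  _phe("B", 1, [0, 0, 5.0], [1, 0, 0])])
    g = ring_geometry(m, ("A", 1), ("B", 1))
    assert g.interplanar_angle > 85.0
    assert g.stacking_class == "edge_to_face"


def test_distant_rings_are_unclassified():
    m = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]),
                  _phe("B", 1, [0, 0, 20.0], [0, 0.17, 1])])
    g = ring_geometry(m, ("A", 1), ("B", 1))
    assert g.stacking_class == "none"


def test_incomplete_ring_is_an_error():
    broken = _phe("A", 1, [0, 0, 0], [0, 0, 1])
    broken.atoms = broken.atoms[:-1]
    m = Model(1, [broken, _phe("B", 1, [0, 0, 3.5], [0, 0, 1])])
    with pytest.raises(GeometryError):
        ring_geometry(m, ("A", 1), ("B", 1))


def test_ring_class_fractions():
    stacked = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]),
                        _phe("B", 1, [0, 0, 3.5], [0, 0, 1])])
    tshape = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]),
                       _phe("B", 1, [0, 0, 5.0], [1, 0, 0])])
    models = []
    for k in range(10):
        m = (stacked if k < 7 else tshape).copy()
        m.model_id = k + 1
        models.append(m)
    ens = StructureEnsemble(models)
    _, fractions = ring_class_series(ens, ("A", 1), ("B", 1))
    assert fractions["parallel"] == pytest.approx(0.7)
    assert fractions["edge_to_face"] == pytest.approx(0.3)


def test_ring_class_invariant_under_rotation():
    stacked = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]),
                        _phe("B", 1, [1.2, 0, 3.4], [0, 0, 1])])
    rng = np.random.default_rng(9)
    models = [stacked]
    for k in range(4):
        models.append(stacked.transform(random_rotation(rng),
                                        rng.uniform(-20, 20, 3)))
        models[-1].model_id = k + 2
    ens = StructureEnsemble(models)
    series, fractions = ring_class_series(ens, ("A", 1), ("B", 1))
    assert len({g.stacking_class for g in series}) == 1
    angles = [g.interplanar_angle for g in series]
    assert max(angles) - min(angles) < 1e-6


def test_interplanar_angle_symmetric(palb2_homodimer):
    g1 = ring_geometry(palb2_homodimer, ("A", 28), ("B", 28))
    g2 = ring_geometry(palb2_homodimer, ("B", 28), ("A", 28))
    assert g1.interplanar_angle == pytest.approx(g2.interplanar_angle, abs=1e-9)


# ---------------------------------------------------------------------------
# Met-aromatic and CH-pi

def _met(chain, num, sd_pos):
    return Residue(chain, num, "MET", [Atom("SD", "S", sd_pos),
                                       Atom("CE", "C", np.add(sd_pos, [1.8, 0, 0]))])


def test_met_aromatic_detection():
    m = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]), _met("B", 5, [0, 0, 5.0])])
    hits = met_aromatic_and_chpi(m)
    kinds = {(h.kind, h.ring_residue) for h in hits}
    assert ("met_aromatic", ("A", 1)) in kinds
    far = Model(1, [_phe("A", 1, [0, 0, 0], [0, 0, 1]), _met("B", 5, [0, 0, 10.0])])
    assert not [h for h in met_aromatic_and_chpi(far) if h.kind == "met_aromatic"]


def test_chpi_detected_in_heterodimer(heterodimer):
    # the partner-chain leucine over the Tyr28 ring face, as in the real
    # PALB2-BRCA1 interface
    hits = met_aromatic_and_chpi(heterodimer)
    chpi = [h for h in hits if h.kind == "ch_pi" and h.ring_residue == ("A", 28)
            and h.donor[0] == "B"]
    assert chpi, "expected a CH-pi contact onto the Tyr28 ring"
    for h in chpi:
        assert h.normal_angle <= 40.0
        assert h.distance <= 4.5
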