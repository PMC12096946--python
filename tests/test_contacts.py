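"""Contact enumeration, classification, native contacts, and statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccdimer.contacts import (atom_contacts, backbone_hbond_count,
                              classify_contact, contact_network, contact_stats,
                              inter_chain_contacts, intra_chain_contacts,
                              native_contact_fraction, residue_contact_count,
                              salt_bridge_occupancy, ContactRecord)
from ccdimer.secondary import HBOND_ENERGY_CUTOFF, backbone_hbond_energy
from ccdimer.structure import (Atom, Model, Residue, Selection,
                               StructureEnsemble, select)
from ccdimer.synthetic import (PerturbationProfile, perturb_ensemble,
                               translate_chain)


def two_atom_model(distance):
    ra = Residue("A", 1, "ALA", [Atom("CB", "C", [0, 0, 0])])
    rb = Residue("B", 1, "ALA", [Atom("CB", "C", [distance, 0, 0])])
    return Model(1, [ra, rb])


def brute_force_count(atoms_a, atoms_b, cutoff, intra):
    """O(N^2) oracle with the same residue/neighbor exclusions."""
    n = 0
    if intra:
        for i in range(len(atoms_a)):
            for j in range(i + 1, len(atoms_a)):
                a, b = atoms_a[i], atoms_a[j]
                if a.chain_id == b.chain_id:
                    if a.seq_number == b.seq_number or \
                            abs(a.seq_number - b.seq_number) < 2:
                        continue
                if np.linalg.norm(a.coord - b.coord) <= cutoff:
                    n += 1
    else:
        for a in atoms_a:
            for b in atoms_b:
                if np.linalg.norm(a.coord - b.coord) <= cutoff:
                    n += 1
    return n


def test_cutoff_boundary():
    m = two_atom_model(6.9)
    ga = select(m, Selection(chains=["A"]))
    gb = select(m, Selection(chains=["B"]))
    assert len(atom_contacts(m, ga, gb, 7.0)) == 1
    m2 = two_atom_model(7.1)
    assert len(atom_contacts(m2, select(m2, Selection(chains=["A"])),
                             select(m2, Selection(chains=["B"])), 7.0)) == 0


def test_partially_overlapping_groups_rejected(palb2_homodimer):
    ga = select(palb2_homodimer, Selection(chains=["A"], heavy_only=True))
    with pytest.raises(ValueError, match="overlap"):
        atom_contacts(palb2_homodimer, ga, ga[: len(ga) // 2], 7.0)


@pytest.mark.parametrize("cutoff", [4.5, 7.0, 10.0])
def test_matches_brute_force_on_dimer(palb2_homodimer, cutoff):
    m = palb2_homodimer
    ga = select(m, Selection(chains=["A"], heavy_only=True))
    gb = select(m, Selection(chains=["B"], heavy_only=True))
    assert len(atom_contacts(m, ga, gb, cutoff)) == \
        brute_force_count(ga, gb, cutoff, intra=False)
    assert len(atom_contacts(m, ga, ga, cutoff)) == \
        brute_force_count(ga, None, cutoff, intra=True)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_matches_brute_force_on_random_clouds(seed):
    # random two-chain atom clouds exercise degenerate geometries the
    # regular coiled coil never produces
    rng = np.random.default_rng(seed)
    residues = []
    for chain in ("A", "B"):
        offset = rng.uniform(-4, 4, 3)
        for rnum in range(1, 11):
            atoms = [Atom(f"C{k}", "C", rng.uniform(-8, 8, 3) + offset)
                     for k in range(rng.integers(1, 5))]
            residues.append(Residue(chain, rnum, "ALA", atoms))
    m = Model(1, residues)
    ga = select(m, Selection(chains=["A"]))
    gb = select(m, Selection(chains=["B"]))
    for cutoff in (4.5, 7.0, 10.0):
        assert len(atom_contacts(m, ga, gb, cutoff)) == \
            brute_force_count(ga, gb, cutoff, intra=False)
        both = select(m, Selection(chains=["A", "B"]))
        assert len(atom_contacts(m, both, both, cutoff)) == \
            brute_force_count(both, None, cutoff, intra=True)


def test_counts_monotone_in_cutoff(palb2_homodimer):
    counts = [len(inter_chain_contacts(palb2_homodimer, "A", "B", c))
              for c in (4.0, 5.5, 7.0, 9.0, 10.0)]
    assert counts == sorted(counts)


def test_counts_invariant_under_rigid_motion_and_chain_swap(palb2_homodimer):
    from conftest import random_rotation
    rng = np.random.default_rng(3)
    moved = palb2_homodimer.transform(random_rotation(rng),
                                      np.array([5.0, -9.0, 2.0]))
    assert len(inter_chain_contacts(moved, "A", "B", 7.0)) == \
        len(inter_chain_contacts(palb2_homodimer, "A", "B", 7.0))
    assert residue_contact_count(palb2_homodimer, "B", "A", 7.0) == \
        residue_contact_count(palb2_homodimer, "A", "B", 7.0)


def test_l24_pair_is_an_interface_contact(palb2_homodimer):
    # the leucine at the dimer center packs against its counterpart
    net = contact_network(palb2_homodimer, "A", "B", 7.0)
    assert (("A", 24), ("B", 24)) in net.edges
    types = net.edges[(("A", 24), ("B", 24))]["types"]
    assert types.get("hydrophobic", 0) >= 1


def test_residue_contact_count_far_chains(palb2_homodimer):
    far = translate_chain(palb2_homodimer, "B", [100.0, 0, 0])
    assert residue_contact_count(far, "A", "B", 7.0) == 0
    with pytest.raises(ValueError):
        residue_contact_count(palb2_homodimer, "A", "A", 7.0)


# ---------------------------------------------------------------------------
# classification

def _residue(chain, num, name, atoms):
    return Residue(chain, num, name, [Atom(n, "", np.array(c)) for n, c in atoms])


def test_salt_bridge_classification():
    lys = _residue("A", 20, "LYS", [("N", [0, 0, 5]), ("CA", [1.5, 0, 5]),
                                    ("CE", [-1, 0, 0.5]), ("NZ", [0, 0, 0])])
    glu = _residue("B", 27, "GLU", [("N", [0, 10, 5]), ("CA", [1.5, 10, 5]),
                                    ("CD", [1, 4.0, 0]), ("OE1", [0, 3.2, 0]),
                                    ("OE2", [2, 4.5, 0])])
    m = Model(1, [lys, glu])
    rec = ContactRecord(("A", 20, "NZ"), ("B", 27, "OE1"), 3.2, "inter_protomer")
    assert classify_contact(rec, m) == "salt_bridge"


def test_hydrophobic_classification():
    l1 = _residue("A", 24, "LEU", [("CG", [0, 0, 1.5]), ("CD1", [0, 0, 0])])
    l2 = _residue("B", 24, "LEU", [("CG", [0, 4.0, -1.5]), ("CD2", [0, 4.0, 0])])
    m = Model(1, [l1, l2])
    rec = ContactRecord(("A", 24, "CD1"), ("B", 24, "CD2"), 4.0, "inter_protomer")
    assert classify_contact(rec, m) == "hydrophobic"


def test_backbone_hbond_classification():
    # ideal N-H...O=C geometry with an explicit amide proton at 160 deg
    donor = _residue("B", 9, "ALA", [("N", [0, 0, 0]), ("H", [0, 0, 1.0]),
                                     ("CA", [1.4, 0, -0.5])])
    acceptor = _residue("A", 5, "ALA", [("C", [0.9, 0.4, 3.8]),
                                        ("O", [0.33, 0.12, 2.75]),
                                        ("CA", [2.2, 0.8, 4.2]),
                                        ("N", [0.5, 0.5, 5.0])])
    # pad the chains so neither partner is a (charged) terminal residue
    pad_a = _residue("A", 6, "ALA", [("CA", [20, 0, 0])])
    pad_b = _residue("B", 8, "ALA", [("CA", [-20, 0, 0])])
    m = Model(1, [acceptor, pad_a, pad_b, donor])
    d = float(np.linalg.norm(np.array([0.33, 0.12, 2.75])))
    rec = ContactRecord(("B", 9, "N"), ("A", 5, "O"), d, "inter_protomer")
    assert classify_contact(rec, m) == "hydrogen_bond"


def test_vdw_fallback_and_unclassified():
    a = _residue("A", 1, "SER", [("CB", [0, 0, 0])])
    b = _residue("B", 1, "SER", [("CB", [4.2, 0, 0])])
    m = Model(1, [a, b])
    rec = ContactRecord(("A", 1, "CB"), ("B", 1, "CB"), 4.2, "inter_protomer")
    assert classify_contact(rec, m) == "van_der_waals"
    rec2 = ContactRecord(("A", 1, "CB"), ("B", 1, "CB"), 6.5, "inter_protomer")
    assert classify_contact(rec2, m) == "unclassified"


# ---------------------------------------------------------------------------
# backbone H-bond counts

@pytest.mark.parametrize("n", [10, 20, 30])
def test_ideal_helix_hbond_ladder(n):
    from ccdimer.peptide import ideal_helix
    m = ideal_helix("A" * n)
    assert backbone_hbond_count(m) == n - 4


def test_extended_chain_has_no_backbone_hbonds(extended20):
    assert backbone_hbond_count(extended20) == 0


def test_hbond_count_matches_energy_scan_oracle(palb2_protomer):
    m = palb2_protomer
    expected = 0
    residues = m.residues
    for donor in residues:
        for acceptor in residues:
            if abs(donor.seq_number - acceptor.seq_number) < 2:
                continue
            e = backbone_hbond_energy(donor, acceptor, m)
            if not math.isnan(e) and e < HBOND_ENERGY_CUTOFF:
                expected += 1
    assert backbone_hbond_count(m) == expected


# ---------------------------------------------------------------------------
# native contacts and occupancy

def test_native_fraction_reference_vs_itself(palb2_homodimer):
    ens = StructureEnsemble([palb2_homodimer])
    fractions, mean = native_contact_fraction(
        ens, palb2_homodimer, Selection(chains=["A"], heavy_only=True),
        Selection(chains=["B"], heavy_only=True))
    assert fractions == [1.0] and mean == 1.0


def test_native_fraction_separated_chains(palb2_homodimer):
    far = translate_chain(palb2_homodimer, "B", [50.0, 0, 0])
    ens = StructureEnsemble([far])
    _, mean = native_contact_fraction(
        ens, palb2_homodimer, Selection(chains=["A"], heavy_only=True),
        Selection(chains=["B"], heavy_only=True))
    assert mean == 0.0


def test_native_fraction_small_perturbation_retains(palb2_homodimer):
    prof = PerturbationProfile(
        sigmas=np.full(len(palb2_homodimer.residues), 0.3), n_models=10, seed=6)
    ens = perturb_ensemble(palb2_homodimer, prof)
    _, mean = native_contact_fraction(
        ens, palb2_homodimer, Selection(chains=["A"], heavy_only=True),
        Selection(chains=["B"], heavy_only=True), cutoff=10.0)
    assert mean >= 0.9


def test_native_fraction_empty_set_is_error(palb2_homodimer):
    far = translate_chain(palb2_homodimer, "B", [200.0, 0, 0])
    with pytest.raises(ValueError, match="empty"):
        native_contact_fraction(StructureEnsemble([far]), far,
                                Selection(chains=["A"], heavy_only=True),
                                Selection(chains=["B"], heavy_only=True))


def test_salt_bridge_occupancy_fractions():
    def frame(dist, mid):
        lys = _residue("A", 20, "LYS", [("CA", [0, 0, 4]), ("NZ", [0, 0, 0])])
        glu = _residue("B", 27, "GLU", [("CA", [0, dist, 4]),
                                        ("OE1", [0, dist, 0]),
                                        ("OE2", [0.5, dist + 1, 0])])
        m = Model(mid, [lys, glu])
        return m
    models = [frame(3.5, k + 1) for k in range(7)] + \
             [frame(8.0, k + 8) for k in range(3)]
    ens = StructureEnsemble(models)
    assert salt_bridge_occupancy(ens, (("A", 20), ("B", 27))) == pytest.approx(0.7)


def test_salt_bridge_occupancy_rejects_nonionizable(palb2_homodimer):
    ens = StructureEnsemble([palb2_homodimer])
    with pytest.raises(ValueError):
        salt_bridge_occupancy(ens, (("A", 24), ("B", 24)))  # Leu/Leu


# ---------------------------------------------------------------------------
# replicate statistics

def test_identical_groups_null():
    st_ = contact_stats([10, 12, 11], [10, 12, 11])
    assert st_.normalized == 1.0
    assert st_.t == 0.0
    assert st_.p == pytest.approx(0.5)


def test_degenerate_separation():
    st_ = contact_stats([10, 10, 10], [5, 5, 5])
    assert st_.normalized == 0.5
    assert st_.p == 0.0


def test_pooled_variance_closed_form():
    wt = [100.0, 98.0, 102.0]
    mut = [80.0, 84.0, 82.0]
    st_ = contact_stats(wt, mut)
    # independent closed-form computation
    m1, m2 = np.mean(wt), np.mean(mut)
    s1, s2 = np.std(wt, ddof=1), np.std(mut, ddof=1)
    sp2 = ((2 * s1 ** 2) + (2 * s2 ** 2)) / 4
    t_exp = (m2 - m1) / math.sqrt(sp2 * (2 / 3))
    from scipy.stats import t as tdist
    p_exp = tdist.sf(abs(t_exp), 4)
    assert st_.t == pytest.approx(t_exp, abs=1e-9)
    assert st_.p == pytest.approx(p_exp, abs=1e-9)
    assert st_.normalized == pytest.approx(m2 / m1, abs=1e-12)
    # and against scipy's two-sample equal-variance test
    from scipy.stats import ttest_ind
    res = ttest_ind(mut, wt, equal_var=True)
    assert st_.t == pytest.approx(res.statistic, abs=1e-9)
    assert st_.p == pytest.approx(res.pvalue / 2, abs=1e-9)


def test_stats_input_validation():
    with pytest.raises(ZeroDivisionError):
        contact_stats([0, 0, 0], [1, 2, 3])
    with pytest.raises(ValueError):
        contact_stats([1.0], [2.0, 3.0])


def test_swap_inverts_normalization():
    a = [100.0, 98.0, 102.0]
    b = [80.0, 84.0, 82.0]
    ab = contact_stats(a, b)
    ba = contact_stats(b, a)
    assert ab.normalized * ba.normalized == pytest.approx(1.0, rel=1e-12)
    assert ab.p == pytest.approx(ba.p, abs=1e-12)
    assert ab.t == pytest.approx(-ba.t, abs=1e-9)
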