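"""Synthetic coiled-coil generator: geometry, mutants, ensembles, unfolding."""

import numpy as np
import pytest

from ccdimer.peptide import dihedral, ideal_helix
from ccdimer.secondary import assign_ss
from ccdimer.structure import Selection, StructureEnsemble, read_structure, select, write_structure
from ccdimer.synthetic import (CrickParams, PerturbationProfile,
                               build_coiled_coil, emulate_unfolding,
                               mutate_residue, perturb_ensemble,
                               PALB2CC_SEQUENCE)


def chain_ca(model, chain_id):
    return np.array([r.atom("CA").coord for r in model.chain_residues(chain_id)])


@pytest.fixture(scope="module")
def parallel_dimer():
    params = CrickParams(orientation="parallel", phase_b=180.0)
    return build_coiled_coil("A" * 28, "A" * 28, params)


@pytest.fixture(scope="module")
def antiparallel_dimer():
    return build_coiled_coil("A" * 28, "A" * 28, CrickParams())


def test_ca_rise_within_helical_bounds(parallel_dimer):
    for cid in ("A", "B"):
        d = np.linalg.norm(np.diff(chain_ca(parallel_dimer, cid), axis=0), axis=1)
        assert d.min() >= 3.7 and d.max() <= 3.9


def test_antiparallel_chain_directions(antiparallel_dimer, parallel_dimer):
    def direction(m, cid):
        ca = chain_ca(m, cid)
        v = ca[-1] - ca[0]
        return v / np.linalg.norm(v)
    assert np.dot(direction(antiparallel_dimer, "A"),
                  direction(antiparallel_dimer, "B")) < 0
    assert np.dot(direction(parallel_dimer, "A"),
                  direction(parallel_dimer, "B")) > 0


def test_superhelix_radius_recovered(antiparallel_dimer):
    # oracle: centroids of four consecutive CA lie on the chain axis, whose
    # distance from the global (z) superhelix axis is the input radius
    for cid in ("A", "B"):
        ca = chain_ca(antiparallel_dimer, cid)
        centers = np.array([ca[i:i + 4].mean(axis=0) for i in range(len(ca) - 3)])
        radius = np.linalg.norm(centers[:, :2], axis=1).mean()
        assert abs(radius - 4.9) <= 0.3


def test_generated_structures_are_l_amino_acids(palb2_homodimer):
    # improper torsion N-C-CA-CB must be near -122.6 deg for L residues
    res = palb2_homodimer.residue("A", 24)
    imp = dihedral(res.atom("N").coord, res.atom("C").coord,
                   res.atom("CA").coord, res.atom("CB").coord)
    assert abs(imp + 122.6) < 10.0


def test_heptad_register_recorded(antiparallel_dimer):
    reg = antiparallel_dimer.heptad_register
    assert reg[1] == "a" and reg[4] == "d" and reg[8] == "a"


def test_nonstandard_residue_rejected():
    with pytest.raises(ValueError):
        build_coiled_coil("AAXAAAA", "AAAAAAA", CrickParams())
    with pytest.raises(ValueError):
        build_coiled_coil("AAA", "AAA", CrickParams())


def test_generated_dimer_roundtrips_through_pdb(tmp_path, palb2_homodimer):
    path = tmp_path / "dimer.pdb"
    write_structure(StructureEnsemble([palb2_homodimer]), path)
    back = read_structure(path)
    assert back.first.topology_signature() == palb2_homodimer.topology_signature()


def test_leucine_zipper_interface_contacts(palb2_homodimer):
    # >= 80% of hydrophobic-ladder residues make inter-chain heavy-atom
    # contact at 7 A -- the leucine-zipper property of the dimer
    from ccdimer.contacts import inter_chain_contacts
    recs = inter_chain_contacts(palb2_homodimer, "A", "B", 7.0)
    touching = {r.atom_a[1] for r in recs} | {r.atom_b[1] for r in recs}
    ladder = [r for r in range(6, 43) if (r - 10) % 7 in (0, 4)]
    frac = len(set(ladder) & touching) / len(ladder)
    assert frac >= 0.8


# ---------------------------------------------------------------------------
# perturbation

def test_zero_sigma_reproduces_input(palb2_protomer):
    prof = PerturbationProfile(sigmas=np.zeros(len(palb2_protomer.residues)),
                               n_models=3, seed=1)
    ens = perturb_ensemble(palb2_protomer, prof)
    ref = np.array([a.coord for a in palb2_protomer.atoms()])
    for m in ens.models:
        assert np.array_equal(ref, np.array([a.coord for a in m.atoms()]))


def test_same_seed_same_ensemble(palb2_protomer):
    prof = PerturbationProfile(sigmas=np.full(len(palb2_protomer.residues), 0.4),
                               n_models=4, seed=99)
    e1 = perturb_ensemble(palb2_protomer, prof)
    e2 = perturb_ensemble(palb2_protomer, prof)
    for m1, m2 in zip(e1.models, e2.models):
        c1 = np.array([a.coord for a in m1.atoms()])
        c2 = np.array([a.coord for a in m2.atoms()])
        assert np.array_equal(c1, c2)


def test_profile_length_mismatch(palb2_protomer):
    with pytest.raises(ValueError, match="sigmas"):
        perturb_ensemble(palb2_protomer,
                         PerturbationProfile(sigmas=np.ones(3), n_models=2, seed=0))


def test_rmsf_matches_sigma_sqrt3(palb2_homodimer):
    # E|N(0, sigma^2 I3)| RMS = sigma * sqrt(3)
    from ccdimer.dynamics import rmsf
    sigma = 0.5
    prof = PerturbationProfile(
        sigmas=np.full(len(palb2_homodimer.residues), sigma),
        n_models=500, seed=12)
    ens = perturb_ensemble(palb2_homodimer, prof)
    profile = rmsf(ens)
    assert abs(profile.values.mean() - sigma * np.sqrt(3)) / (sigma * np.sqrt(3)) < 0.05


# ---------------------------------------------------------------------------
# mutation

def test_same_residue_mutation_keeps_backbone_and_name(palb2_homodimer):
    mut = mutate_residue(palb2_homodimer, "A", 24, "LEU")
    assert mut.residue("A", 24).name == "LEU"
    for res in palb2_homodimer.residues:
        for name in ("N", "CA", "C", "O"):
            d = np.linalg.norm(mut.atom(res.chain_id, res.seq_number, name).coord -
                               res.atom(name).coord)
            assert d == 0.0


def test_proline_mutation_topology(palb2_homodimer):
    mut = mutate_residue(palb2_homodimer, "A", 35, "P")
    names = {a.name for a in mut.residue("A", 35).atoms}
    assert names == {"N", "CA", "C", "O", "CB", "CG", "CD"}


def test_tyr_to_cys_heavy_atom_count(palb2_homodimer):
    assert len(palb2_homodimer.residue("A", 28).heavy_atoms()) == 12
    mut = mutate_residue(palb2_homodimer, "A", 28, "CYS")
    assert len(mut.residue("A", 28).heavy_atoms()) == 6


def test_mutation_input_errors(palb2_homodimer):
    with pytest.raises(ValueError):
        mutate_residue(palb2_homodimer, "A", 24, "XYZ")
    with pytest.raises(ValueError):
        mutate_residue(palb2_homodimer, "A", 999, "ALA")


def test_interface_ala_mutation_reduces_contacts(palb2_homodimer):
    # removing interface side chains must strictly decrease inter-protomer
    # counts -- the qualitative single-mutant phenotype
    from ccdimer.contacts import inter_chain_contacts
    before = len(inter_chain_contacts(palb2_homodimer, "A", "B", 7.0))
    mut = palb2_homodimer
    for chain in ("A", "B"):
        for pos in (17, 21, 24, 28):
            mut = mutate_residue(mut, chain, pos, "ALA")
    after = len(inter_chain_contacts(mut, "A", "B", 7.0))
    assert after < before


# ---------------------------------------------------------------------------
# unfolding emulation

def test_unfolding_start_beyond_chain_is_identity(palb2_protomer):
    ens = emulate_unfolding(palb2_protomer, "A", 500, n_models=3, seed=0)
    ref = np.array([a.coord for a in palb2_protomer.atoms()])
    for m in ens.models:
        assert np.allclose(ref, np.array([a.coord for a in m.atoms()]))


def test_unfolding_reduces_window_helicity(palb2_protomer):
    ens = emulate_unfolding(palb2_protomer, "A", 30, n_models=8, seed=4)
    window = [("A", r, "") for r in range(30, 43)]

    def win_hel(model):
        labels = assign_ss(model).labels
        return np.mean([labels.get(k) == "H" for k in window])

    assert win_hel(ens.models[-1]) < win_hel(ens.models[0])


def test_full_randomization_abolishes_window_helix(palb2_protomer):
    ens = emulate_unfolding(palb2_protomer, "A", 7, n_models=8, seed=2)
    window = [("A", r, "") for r in range(7, 43)]
    for model in ens.models[-2:]:   # last quarter of the ensemble
        labels = assign_ss(model).labels
        frac = np.mean([labels.get(k) == "H" for k in window])
        assert frac < 0.2


def test_unfolding_preserves_bond_geometry(palb2_protomer):
    ens = emulate_unfolding(palb2_protomer, "A", 20, n_models=5, seed=3)
    ca = np.array([r.atom("CA").coord
                   for r in ens.models[-1].chain_residues("A")])
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert d.min() > 3.5 and d.max() < 4.1
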