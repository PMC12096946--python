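"""Rigid-body superposition, RMSD/RMSF, and replicate summaries.

Superposition is the Kabsch least-squares fit.  RMSF is computed about
the iteratively refined ensemble mean structure, following standard
trajectory-analysis practice: superpose all models on the current mean,
recompute the mean, repeat (three rounds converge at these sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import Model, Selection, StructureEnsemble, select


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int

    def apply(self, model: Model) -> Model:
        return model.transform(self.rotation, self.translation)


def _kabsch(mobile: np.ndarray, reference: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def superpose(mobile_model: Model, reference_model: Model,
              selection: Selection | None = None) -> SuperpositionResult:
    """Optimal rigid transform of ``mobile`` onto ``reference``.

    The selection must resolve to the same atoms (addresses) in both
    models; default is all CA atoms.
    """
    if selection is None:
        selection = Selection(atom_names=["CA"])
    atoms_m = select(mobile_model, selection)
    atoms_r = select(reference_model, selection)
    addr = lambda a: (a.chain_id, a.seq_number, a.insertion_code, a.name)
    if [addr(a) for a in atoms_m] != [addr(a) for a in atoms_r]:
        raise ValueError("selection does not map 1:1 between the models")
    if len(atoms_m) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    rot, trans, rmsd = _kabsch(np.array([a.coord for a in atoms_m]),
                               np.array([a.coord for a in atoms_r]))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               n_atoms=len(atoms_m))


@dataclass
class RmsfProfile:
    atoms: list[tuple]      # (chain, resnum, icode, name)
    values: np.ndarray      # A, one per selected atom

    def by_residue(self) -> dict[tuple, float]:
        return {(a[0], a[1]): v for a, v in zip(self.atoms, self.values)}


def rmsf(ensemble: StructureEnsemble, selection: Selection | None = None,
         mean_iterations: int = 3) -> RmsfProfile:
    """Per-atom RMSF about the refined ensemble mean (default: all CA)."""
    if len(ensemble.models) < 2:
        raise ValueError("RMSF needs at least two models")
    if selection is None:
        selection = Selection(atom_names=["CA"])
    per_model = []
    addresses = None
    for model in ensemble.models:
        atoms = select(model, selection)
        addr = [(a.chain_id, a.seq_number, a.insertion_code, a.name) for a in atoms]
        if addresses is None:
            addresses = addr
        elif addr != addresses:
            raise ValueError("selection is not topology-consistent across models")
        per_model.append(np.array([a.coord for a in atoms]))
    x = np.stack(per_model)               # (n_models, n_atoms, 3)
    mean = x[0].copy()
    for _ in range(mean_iterations):
        aligned = np.empty_like(x)
        for k in range(x.shape[0]):
            rot, trans, _ = _kabsch(x[k], mean)
            aligned[k] = x[k] @ rot.T + trans
        mean = aligned.mean(axis=0)
    dev = aligned - mean
    values = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    return RmsfProfile(atoms=addresses, values=values)


@dataclass
class ReplicateSummary:
    replicate_means: np.ndarray
    mean: float
    sd: float   # sample s.d. (n-1) of replicate means


def replicate_summary(per_replicate_series: Sequence[Sequence[float]]
                      ) -> ReplicateSummary:
    """Mean of each replicate series, their group mean and sample s.d."""
    if len(per_replicate_series) < 2:
        raise ValueError("need at least two replicates")
    means = np.array([np.mean(s) for s in per_replicate_series], float)
    return ReplicateSummary(replicate_means=means, mean=float(means.mean()),
                            sd=float(means.std(ddof=1)))
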