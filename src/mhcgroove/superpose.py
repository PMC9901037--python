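"""Rigid-body superposition and per-position Cα displacement.

Structure pairs are compared by least-squares (Kabsch) superposition on a fit
selection — by convention the heavy-chain α1α2 Cα atoms (residues 1-180)
restricted to residues modeled in both structures — followed by Euclidean
distance between target Cα atoms, e.g. the peptide P1 shift between the
long-peptide and control complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomSelector, StructureModel, StructureError

#: Default fit selection: heavy-chain α1α2 domain residues in author numbering.
ALPHA12_RESIDUES = range(1, 181)


class SuperpositionError(ValueError):
    """Raised for under-determined or degenerate superposition problems."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray  # 3x3 proper orthonormal
    translation: np.ndarray  # Å
    rmsd: float  # Å over the fit selection
    n_atoms_fit: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns the proper rotation R and translation t minimising
    ``sum |reference_i - (R @ mobile_i + t)|^2``, with the post-fit RMSD.
    Requires >= 3 non-collinear point pairs.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise SuperpositionError("mobile and reference must be matching (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >= 3 point pairs, got {n}")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinear points leave a free rotation about the common axis
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise SuperpositionError("degenerate (collinear) fit geometry")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    # recompute the residual directly: the rssd reported by align_vectors
    # loses precision near zero
    rmsd = float(np.sqrt(((mob @ R.T + t - ref) ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms_fit=n)


def _paired_ca(
    model_a: StructureModel, model_b: StructureModel, fit: AtomSelector
) -> tuple[np.ndarray, np.ndarray]:
    atoms_a = {(a.chain, a.resnum): a for a in fit.resolve(model_a) if a.name == "CA"}
    atoms_b = {(a.chain, a.resnum): a for a in fit.resolve(model_b) if a.name == "CA"}
    common = [k for k in atoms_a if k in atoms_b]
    if not common:
        raise SuperpositionError("fit selections share no Cα atoms")
    ca_a = np.array([atoms_a[k].xyz for k in common])
    ca_b = np.array([atoms_b[k].xyz for k in common])
    return ca_a, ca_b


def ca_displacement(
    model_a: StructureModel,
    model_b: StructureModel,
    fit: AtomSelector,
    target: tuple[str, int],
    target_b: tuple[str, int] | None = None,
) -> float:
    """Cα shift (Å) of ``target`` between two structures after superposition.

    ``model_b`` is superposed onto ``model_a`` using the Cα atoms of the fit
    selection resolved in both models (intersection of modeled residues);
    the Euclidean distance between the target Cα atoms is returned.
    ``target_b`` names the corresponding residue in ``model_b`` when author
    numbering differs between the structures (e.g. P1 of a long peptide vs
    P1 of its short control); by default ``target`` is used in both.
    """
    chain_a, resnum_a = target
    chain_b, resnum_b = target_b if target_b is not None else target
    ca_a, ca_b = _paired_ca(model_a, model_b, fit)
    result = kabsch_superpose(ca_b, ca_a)
    try:
        tgt_a = model_a.atom(chain_a, resnum_a, "CA").xyz
        tgt_b = model_b.atom(chain_b, resnum_b, "CA").xyz
    except StructureError as exc:
        raise SuperpositionError(f"target Cα missing: {exc}") from exc
    return float(np.linalg.norm(tgt_a - result.apply(tgt_b[None, :])[0]))


def default_fit_selector(heavy_chain: str) -> AtomSelector:
    """Heavy-chain α1α2 Cα fit selection (residues 1-180)."""
    return AtomSelector(chain=heavy_chain, residues=ALPHA12_RESIDUES, atom_names=("CA",))
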