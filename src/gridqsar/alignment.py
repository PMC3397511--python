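"""Rigid-body superposition of a compound series onto a template molecule.

Every compound is least-squares fitted (Kabsch) onto the template over the
atoms matched by a common-scaffold substructure pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_dataset import Molecule, MoleculeSet

__all__ = ["RigidTransform", "AlignmentResult", "kabsch_superpose", "scaffold_align"]

_MAX_MATCHES = 64


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x @ R.T + t``."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    pairing: list[tuple[int, int]] | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of paired atoms (minimizes paired RMSD).

    ``pairing`` lists (mobile index, reference index) pairs; by default the
    two coordinate sets are paired row-by-row. Requires >= 3 non-collinear
    pairs.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if pairing is None:
        if len(mobile) != len(reference):
            raise ValueError("unpaired coordinate sets of different lengths")
        pairing = [(i, i) for i in range(len(mobile))]
    if len(pairing) < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    mi = np.array([p[0] for p in pairing])
    ri = np.array([p[1] for p in pairing])
    P = mobile[mi]
    Q = reference[ri]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear (or degenerate) reference points leave the rotation
    # underdetermined about the common axis
    if np.linalg.matrix_rank(Qc, tol=1e-8) < 2 or np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("paired atoms are collinear; superposition is underdetermined")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


@dataclass
class AlignmentResult:
    molecules: MoleculeSet
    report: pd.DataFrame  # columns: compound_id, rmsd, n_matched
    failures: list[str]

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)


def _scaffold_matches(mol: Molecule, pattern: Chem.Mol | None) -> list[tuple[int, ...]]:
    if pattern is not None and mol.rdmol is not None:
        matches = mol.rdmol.GetSubstructMatches(pattern, uniquify=True, maxMatches=_MAX_MATCHES)
        return [tuple(m) for m in matches]
    if mol.scaffold_atom_map is not None:
        keys = sorted(mol.scaffold_atom_map)
        return [tuple(mol.scaffold_atom_map[k] for k in keys)]
    return []


def scaffold_align(
    molset: MoleculeSet,
    template: Molecule,
    scaffold: str | None = None,
    *,
    force: bool = False,
) -> AlignmentResult:
    """Superpose every compound onto ``template`` over the common scaffold.

    ``scaffold`` is a SMARTS pattern matched in both template and compound;
    molecules without an RDKit graph fall back to their ``scaffold_atom_map``.
    Multiple substructure matches are resolved by the lowest-RMSD fit.
    Compounds with no match are reported as failures and excluded unless
    ``force`` is set (then kept untransformed).
    """
    pattern = None
    if scaffold is not None:
        pattern = Chem.MolFromSmarts(scaffold)
        if pattern is None:
            raise ValueError(f"invalid scaffold SMARTS {scaffold!r}")
    tmpl_matches = _scaffold_matches(template, pattern)
    if not tmpl_matches:
        raise ValueError(f"scaffold pattern does not match template {template.id!r}")
    tmpl_atoms = tmpl_matches[0]
    ref = template.coords[list(tmpl_atoms)]

    aligned: list[Molecule] = []
    rows: list[dict] = []
    failures: list[str] = []
    for mol in molset:
        matches = _scaffold_matches(mol, pattern)
        if not matches:
            failures.append(mol.id)
            if force:
                aligned.append(mol)
                rows.append({"compound_id": mol.id, "rmsd": np.nan, "n_matched": 0})
            continue
        best: tuple[RigidTransform, float] | None = None
        for match in matches:
            transform, rmsd = kabsch_superpose(
                mol.coords[list(match)], ref
            )
            if best is None or rmsd < best[1]:
                best = (transform, rmsd)
        transform, rmsd = best
        aligned.append(mol.with_coords(transform.apply(mol.coords)))
        rows.append({"compound_id": mol.id, "rmsd": rmsd, "n_matched": len(tmpl_atoms)})
    report = pd.DataFrame(rows, columns=["compound_id", "rmsd", "n_matched"])
    return AlignmentResult(molecules=MoleculeSet(aligned), report=report, failures=failures)
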