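"""Rigid-body alignment onto a template via the maximum common substructure.

Every molecule is superposed on a chosen template (typically the most
potent compound of the series) over their maximum common substructure,
using the optimal least-squares (Kabsch) rotation restricted to proper
rotations.  Only heavy atoms participate in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem import Molecule

__all__ = [
    "AlignmentResult",
    "find_common_substructure",
    "enumerate_substructure_mappings",
    "rigid_fit",
    "align_to_template",
]


@dataclass
class AlignmentResult:
    molecule_id: str
    pairs: list[tuple[int, int]]  # (template atom idx, molecule atom idx)
    rotation: np.ndarray          # 3x3, det = +1
    translation: np.ndarray       # 3-vector, Å
    rmsd: float                   # Å over matched atoms
    conformer: int                # id of the aligned conformer added to the molecule


def _heavy_copy(mol: Molecule) -> tuple[Chem.Mol, list[int]]:
    """Hydrogen-free copy plus mapping heavy-copy index -> original index."""
    idx_map = mol.heavy_atom_indices()
    return Chem.RemoveHs(Chem.Mol(mol.rdmol)), idx_map


def enumerate_substructure_mappings(template: Molecule, mol: Molecule,
                                    query: Chem.Mol | None = None,
                                    max_matches: int = 64
                                    ) -> list[list[tuple[int, int]]]:
    """All heavy-atom MCS mappings as lists of (template, molecule) pairs.

    ``query`` short-circuits the MCS search when the common scaffold is
    already known (e.g. a designed congeneric series).
    """
    t_heavy, t_map = _heavy_copy(template)
    m_heavy, m_map = _heavy_copy(mol)
    if query is None:
        res = rdFMCS.FindMCS(
            [t_heavy, m_heavy],
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            timeout=30,
        )
        if res.canceled and res.numAtoms < 3:
            raise ValueError("MCS search failed")
        query = Chem.MolFromSmarts(res.smartsString)
    t_matches = t_heavy.GetSubstructMatches(query, uniquify=False,
                                            maxMatches=max_matches)
    m_matches = m_heavy.GetSubstructMatches(query, uniquify=False,
                                            maxMatches=max_matches)
    if not t_matches or not m_matches:
        raise ValueError(
            f"{mol.id}: common substructure not matchable in both molecules"
        )
    if query.GetNumAtoms() < 3:
        raise ValueError(
            f"{mol.id}: common substructure has fewer than 3 atoms"
        )
    mappings = []
    for tm in t_matches:
        for mm in m_matches:
            mappings.append(
                [(t_map[ti], m_map[mi]) for ti, mi in zip(tm, mm)]
            )
    return mappings


def find_common_substructure(template: Molecule, mol: Molecule,
                             query: Chem.Mol | None = None
                             ) -> list[tuple[int, int]]:
    """Single MCS atom-pair list; ties broken by lowest template-index order."""
    mappings = enumerate_substructure_mappings(template, mol, query=query)
    return min(mappings, key=lambda pairs: [p[0] for p in pairs])


def _check_not_collinear(P: np.ndarray) -> None:
    centered = P - P.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("matched atoms are collinear; rigid fit is underdetermined")


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t with R@p + t ≈ q.

    Returns (R, t, rmsd).  Improper rotations (reflections) are excluded by
    flipping the sign of the smallest singular direction when needed.
    """
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def rigid_fit(template: Molecule, mol: Molecule,
              pairs: list[tuple[int, int]],
              template_conformer: int = 0,
              mol_conformer: int = 0) -> AlignmentResult:
    """Least-squares superposition of ``mol`` onto ``template`` over ``pairs``.

    The aligned coordinates are appended to ``mol`` as a new conformer.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched atom pairs")
    t_xyz = template.coords(template_conformer)
    m_xyz = mol.coords(mol_conformer)
    P = m_xyz[[mi for _, mi in pairs]]
    Q = t_xyz[[ti for ti, _ in pairs]]
    _check_not_collinear(Q)
    _check_not_collinear(P)
    R, t, rmsd = kabsch(P, Q)
    conf_id = mol.add_conformer(m_xyz @ R.T + t)
    return AlignmentResult(mol.id, list(pairs), R, t, rmsd, conf_id)


def align_to_template(template: Molecule, mols: list[Molecule],
                      query: Chem.Mol | None = None,
                      template_conformer: int = 0,
                      mol_conformer: int = 0) -> list[AlignmentResult]:
    """Align each molecule onto the template over the MCS.

    When several MCS mappings tie on atom count, all are scored by post-fit
    RMSD and the lowest wins (deterministic tie-break: lowest RMSD, then
    lexicographic template-index order).
    """
    results = []
    for mol in mols:
        mappings = enumerate_substructure_mappings(template, mol, query=query)
        best = None
        for pairs in sorted(mappings, key=lambda prs: [p[0] for p in prs]):
            t_xyz = template.coords(template_conformer)
            m_xyz = mol.coords(mol_conformer)
            P = m_xyz[[mi for _, mi in pairs]]
            Q = t_xyz[[ti for ti, _ in pairs]]
            try:
                _check_not_collinear(Q)
                _check_not_collinear(P)
            except ValueError:
                continue
            R, t, rmsd = kabsch(P, Q)
            if best is None or rmsd < best[0] - 1e-12:
                best = (rmsd, pairs, R, t)
        if best is None:
            raise ValueError(f"{mol.id}: no usable (non-collinear) MCS mapping")
        rmsd, pairs, R, t = best
        conf_id = mol.add_conformer(mol.coords(mol_conformer) @ R.T + t)
        results.append(AlignmentResult(mol.id, pairs, R, t, rmsd, conf_id))
    return results
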