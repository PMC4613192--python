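"""Molecule and activity I/O, partial charges, and calculated logP.

Molecules are thin wrappers around RDKit ``Mol`` objects with explicit
hydrogens and at least one 3D conformer.  Partial charges follow the
Gasteiger PEOE scheme (the sigma component of the classic
"Gasteiger-Hückel" combination; the π correction is not applied).
Calculated logP uses the Crippen atom-contribution method, which plays the
same role as a whole-molecule hydrophobicity descriptor (ClogP) in QSAR
model building.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen

__all__ = [
    "Molecule",
    "ActivityRecord",
    "read_molecules",
    "write_molecules",
    "read_activities",
    "assign_charges",
    "compute_clogp",
    "smiles_to_molecule",
]

_CHARGE_PROP = "_PEOECharge"


@dataclass
class Molecule:
    """A small molecule with explicit hydrogens and 3D conformer(s).

    Attributes
    ----------
    id : str
        Unique identifier within a dataset.
    rdmol : rdkit.Chem.Mol
        Backing RDKit molecule.  All conformers live here.
    properties : dict
        Free-form scalar properties (e.g. ``clogp``).
    """

    id: str
    rdmol: Chem.Mol
    properties: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.rdmol.GetAtoms()]

    @property
    def n_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    def coords(self, conformer: int = 0) -> np.ndarray:
        """Cartesian coordinates (Å) of the given conformer, shape (n_atoms, 3)."""
        conf = self.rdmol.GetConformer(conformer)
        return np.array(conf.GetPositions(), dtype=float)

    def set_coords(self, xyz: np.ndarray, conformer: int = 0) -> None:
        conf = self.rdmol.GetConformer(conformer)
        for i, (x, y, z) in enumerate(np.asarray(xyz, dtype=float)):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))

    def add_conformer(self, xyz: np.ndarray) -> int:
        """Append a conformer with the given coordinates; returns its id."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(f"conformer shape {xyz.shape} != ({self.n_atoms}, 3)")
        conf = Chem.Conformer(self.n_atoms)
        for i, (x, y, z) in enumerate(xyz):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        return self.rdmol.AddConformer(conf, assignId=True)

    @property
    def charges(self) -> np.ndarray | None:
        """Partial atomic charges (e), or None before `assign_charges`."""
        atoms = list(self.rdmol.GetAtoms())
        if not atoms or not atoms[0].HasProp(_CHARGE_PROP):
            return None
        return np.array([a.GetDoubleProp(_CHARGE_PROP) for a in atoms])

    @property
    def formal_charge(self) -> int:
        return Chem.GetFormalCharge(self.rdmol)

    def heavy_atom_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1]


@dataclass(frozen=True)
class ActivityRecord:
    """Measured potency of one molecule.

    ``pic50`` is −log10 of the molar IC50; higher is more potent.  On
    construction a missing member of the (ic50, pic50) pair is filled in
    from the other, and an inconsistent pair raises.
    """

    molecule_id: str
    ic50: float | None = None
    pic50: float | None = None

    def __post_init__(self):
        ic50, pic50 = self.ic50, self.pic50
        if ic50 is None and pic50 is None:
            raise ValueError(f"{self.molecule_id}: need ic50 and/or pic50")
        if ic50 is not None and ic50 <= 0:
            raise ValueError(f"{self.molecule_id}: ic50 must be positive molar")
        if ic50 is None:
            object.__setattr__(self, "ic50", 10.0 ** (-pic50))
        elif pic50 is None:
            object.__setattr__(self, "pic50", -math.log10(ic50))
        elif abs(pic50 + math.log10(ic50)) > 1e-9:
            raise ValueError(
                f"{self.molecule_id}: pic50={pic50} inconsistent with ic50={ic50}"
            )


def _unique_ids(raw: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in raw:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def smiles_to_molecule(smiles: str, mol_id: str, seed: int = 20150825) -> Molecule:
    """Parse a SMILES, add hydrogens, and embed one seeded 3D conformer (ETKDG)."""
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"unparseable SMILES for {mol_id!r}: {smiles!r}")
    rd = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed & 0x7FFFFFFF
    if AllChem.EmbedMolecule(rd, params) != 0:
        # fall back to random-coordinate embedding for awkward topologies
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rd, params) != 0:
            raise ValueError(f"3D embedding failed for {mol_id!r}")
    rd.SetProp("_Name", mol_id)
    return Molecule(id=mol_id, rdmol=rd)


def _finalize(mols: list[Molecule]) -> list[Molecule]:
    if not mols:
        raise ValueError("no molecules could be read")
    ids = _unique_ids([m.id for m in mols])
    for m, mid in zip(mols, ids):
        m.id = mid
        m.rdmol.SetProp("_Name", mid)
    return mols


def _split_mol2_blocks(text: str) -> list[str]:
    marker = "@<TRIPOS>MOLECULE"
    chunks = text.split(marker)
    return [marker + c for c in chunks[1:]]


def read_molecules(path: str | Path, fmt: str | None = None,
                   seed: int = 20150825) -> list[Molecule]:
    """Read molecules from an SDF, MOL2 or SMILES file.

    SMILES input (one ``smiles [id]`` per line) gets a deterministic seeded
    3D embedding; SDF/MOL2 coordinates are taken as-is.  Hydrogens are made
    explicit.  Duplicate ids are suffixed deterministically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".sdf": "sdf", ".sd": "sdf", ".mol2": "mol2",
               ".smi": "smiles", ".smiles": "smiles"}.get(path.suffix.lower(), "sdf")
    fmt = fmt.lower()
    if not path.read_text().strip():
        raise ValueError(f"{path}: no molecules could be read")
    mols: list[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, rd in enumerate(supplier):
            if rd is None:
                raise ValueError(f"{path}: unparseable SDF record {i + 1}")
            rd = Chem.AddHs(rd, addCoords=True)
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
            mols.append(Molecule(id=name.strip() or f"mol{i + 1}", rdmol=rd))
    elif fmt == "mol2":
        for i, block in enumerate(_split_mol2_blocks(path.read_text())):
            rd = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if rd is None:
                raise ValueError(f"{path}: unparseable MOL2 record {i + 1}")
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
            mols.append(Molecule(id=name.strip() or f"mol{i + 1}", rdmol=rd))
    elif fmt == "smiles":
        lines = [ln.strip() for ln in path.read_text().splitlines()]
        lines = [ln for ln in lines if ln and not ln.startswith("#")]
        for i, line in enumerate(lines):
            parts = line.split()
            mol_id = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            try:
                mols.append(smiles_to_molecule(parts[0], mol_id, seed=seed + i))
            except ValueError as exc:
                raise ValueError(f"{path}: record {i + 1}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _finalize(mols)


def write_molecules(mols: Sequence[Molecule], path: str | Path,
                    conformer: int = 0) -> None:
    """Write molecules to a multi-record V2000 SDF using the given conformer."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for m in mols:
            m.rdmol.SetProp("_Name", m.id)
            for key, val in m.properties.items():
                m.rdmol.SetProp(str(key), str(val))
            writer.write(m.rdmol, confId=conformer)
    finally:
        writer.close()


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read activities from a CSV with columns id and ic50_molar and/or pic50."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "id" not in cols:
        raise ValueError(f"{path}: missing 'id' column")
    out = []
    for _, row in df.iterrows():
        ic50 = row[cols["ic50_molar"]] if "ic50_molar" in cols else None
        pic50 = row[cols["pic50"]] if "pic50" in cols else None
        ic50 = None if ic50 is None or pd.isna(ic50) else float(ic50)
        pic50 = None if pic50 is None or pd.isna(pic50) else float(pic50)
        out.append(ActivityRecord(str(row[cols["id"]]), ic50=ic50, pic50=pic50))
    if not out:
        raise ValueError(f"{path}: no activity records")
    return out


def assign_charges(mol: Molecule) -> Molecule:
    """Assign Gasteiger PEOE partial charges in place (also returned).

    Charges sum to the net formal charge.  An element outside the PEOE
    parameterization yields non-finite charges and raises, naming it.
    """
    try:
        AllChem.ComputeGasteigerCharges(mol.rdmol, throwOnParamFailure=True)
    except Exception as exc:
        missing = sorted({a.GetSymbol() for a in mol.rdmol.GetAtoms()
                          if a.GetAtomicNum() > 53 or a.GetAtomicNum() == 0}
                         or set(mol.elements))
        raise ValueError(
            f"{mol.id}: no PEOE parameters for element(s) {missing}"
        ) from exc
    charges = []
    for atom in mol.rdmol.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(q):
            raise ValueError(
                f"{mol.id}: no PEOE parameters for element {atom.GetSymbol()}"
            )
        charges.append(q)
    # renormalize the tiny numerical drift so the sum is exactly the formal charge
    drift = (sum(charges) - mol.formal_charge) / len(charges)
    for atom, q in zip(mol.rdmol.GetAtoms(), charges):
        atom.SetDoubleProp(_CHARGE_PROP, q - drift)
    return mol


def compute_clogp(mol: Molecule) -> float:
    """Crippen atom-contribution logP; stored under ``properties['clogp']``."""
    value = Crippen.MolLogP(mol.rdmol)
    if not np.isfinite(value):
        raise ValueError(f"{mol.id}: logP contribution undefined")
    mol.properties["clogp"] = float(value)
    return float(value)
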