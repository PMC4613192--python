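import numpy as np
import pytest
from rdkit import Chem
from rdkit import RDLogger

from qsar3d.chem import Molecule, assign_charges, compute_clogp, smiles_to_molecule
from qsar3d.pls import PLSQSAR
from qsar3d.synthetic import SyntheticSpec, generate_series

RDLogger.DisableLog("rdApp.*")


def molecule_from_smiles(smiles: str, mol_id: str, seed: int = 7,
                         charges: bool = True) -> Molecule:
    mol = smiles_to_molecule(smiles, mol_id, seed=seed)
    if charges:
        assign_charges(mol)
    compute_clogp(mol)
    return mol


def single_atom_molecule(symbol: str = "C", position=(0.0, 0.0, 0.0)) -> Molecule:
    """A bare atom with one conformer — handy for analytic field checks."""
    rw = Chem.RWMol()
    atom = Chem.Atom(symbol)
    atom.SetNoImplicit(True)
    rw.AddAtom(atom)
    rd = rw.GetMol()
    Chem.SanitizeMol(rd)
    mol = Molecule(id=f"atom_{symbol}", rdmol=rd)
    mol.add_conformer(np.array([position], dtype=float))
    return mol


@pytest.fixture(scope="session")
def ethanol():
    return molecule_from_smiles("CCO", "ethanol")


@pytest.fixture(scope="session")
def pyridine():
    return molecule_from_smiles("c1ccncc1", "pyridine")


@pytest.fixture(scope="session")
def imidazole():
    return molecule_from_smiles("c1c[nH]cn1", "imidazole")


@pytest.fixture(scope="session")
def small_series():
    """12-molecule noiseless synthetic series (fast, reused widely)."""
    return generate_series(SyntheticSpec(n_molecules=12, seed=1))


@pytest.fixture(scope="session")
def recovery_series():
    """The zero-noise 30-molecule recovery study condition."""
    return generate_series(SyntheticSpec(n_molecules=30, seed=7))


@pytest.fixture(scope="session")
def recovery_fit(recovery_series):
    model = PLSQSAR.from_descriptor_matrix(recovery_series.descriptors,
                                           recovery_series.activities)
    return model.fit_loo(c_max=10)
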