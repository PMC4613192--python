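"""Training/test splitting with a Kohonen self-organizing map.

A SOM clusters the dataset in a ~40-dimensional descriptor space; the test
set is then drawn per occupied neuron so that (1) it holds at least five
molecules, (2) test points stay close to training points in descriptor
space, and (3) the training set covers the whole occupied map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, rdMolDescriptors

from .chem import Molecule

__all__ = [
    "SplitAssignment",
    "compute_descriptors",
    "SelfOrganizingMap",
    "split_dataset",
    "occupancy_map",
]

# Compact stand-in descriptor set: constitutional counts, topological
# indices, hydrophobicity and polar-surface terms.  Splitting only needs a
# diverse descriptor space, not any specific vendor set.
_DESCRIPTOR_FUNCS = [
    ("MolWt", Descriptors.MolWt),
    ("HeavyAtomCount", Descriptors.HeavyAtomCount),
    ("NumHAcceptors", Descriptors.NumHAcceptors),
    ("NumHDonors", Descriptors.NumHDonors),
    ("NumRotatableBonds", Descriptors.NumRotatableBonds),
    ("RingCount", Descriptors.RingCount),
    ("NumAromaticRings", rdMolDescriptors.CalcNumAromaticRings),
    ("NumSaturatedRings", rdMolDescriptors.CalcNumSaturatedRings),
    ("NumAliphaticRings", rdMolDescriptors.CalcNumAliphaticRings),
    ("NumHeteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("LabuteASA", rdMolDescriptors.CalcLabuteASA),
    ("MolLogP", Crippen.MolLogP),
    ("MolMR", Crippen.MolMR),
    ("BalabanJ", GraphDescriptors.BalabanJ),
    ("BertzCT", GraphDescriptors.BertzCT),
    ("Chi0", GraphDescriptors.Chi0),
    ("Chi1", GraphDescriptors.Chi1),
    ("Chi0v", GraphDescriptors.Chi0v),
    ("Chi1v", GraphDescriptors.Chi1v),
    ("Chi2v", GraphDescriptors.Chi2v),
    ("Chi3v", GraphDescriptors.Chi3v),
    ("Chi4v", GraphDescriptors.Chi4v),
    ("Kappa1", GraphDescriptors.Kappa1),
    ("Kappa2", GraphDescriptors.Kappa2),
    ("Kappa3", GraphDescriptors.Kappa3),
    ("HallKierAlpha", GraphDescriptors.HallKierAlpha),
    ("NHOHCount", Descriptors.NHOHCount),
    ("NOCount", Descriptors.NOCount),
    ("ExactMolWt", Descriptors.ExactMolWt),
    ("NumValenceElectrons", Descriptors.NumValenceElectrons),
    ("MaxPartialCharge", Descriptors.MaxPartialCharge),
    ("MinPartialCharge", Descriptors.MinPartialCharge),
]
_ELEMENT_COUNTS = ["C", "N", "O", "S", "F", "Cl", "Br"]


@dataclass(frozen=True)
class SplitAssignment:
    molecule_id: str
    neuron: tuple[int, int]
    role: str  # "training" | "test"


def compute_descriptors(mols: list[Molecule], standardize: bool = True
                        ) -> tuple[np.ndarray, list[str]]:
    """Descriptor matrix (molecules × descriptors) for SOM splitting.

    Constant columns are removed; remaining columns are standardized to
    zero mean / unit variance unless ``standardize`` is False.
    """
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules")
    rows, names = [], None
    for m in mols:
        vals, nms = [], []
        for name, fn in _DESCRIPTOR_FUNCS:
            try:
                v = float(fn(m.rdmol))
            except Exception:
                v = 0.0
            vals.append(v if np.isfinite(v) else 0.0)
            nms.append(name)
        counts = {el: 0 for el in _ELEMENT_COUNTS}
        for a in m.rdmol.GetAtoms():
            if a.GetSymbol() in counts:
                counts[a.GetSymbol()] += 1
        for el in _ELEMENT_COUNTS:
            vals.append(float(counts[el]))
            nms.append(f"n{el}")
        rows.append(vals)
        names = nms
    X = np.asarray(rows, dtype=float)
    keep = X.std(axis=0) > 1e-12
    if not keep.any():
        raise ValueError("descriptor matrix is all-constant")
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X, names


class SelfOrganizingMap:
    """Rectangular-grid Kohonen map with Gaussian neighborhood.

    Learning rate and neighborhood radius decay linearly over a fixed
    number of epochs; weights are initialized uniformly within the data
    range from a seeded generator, so training is fully reproducible.
    """

    def __init__(self, rows: int = 6, cols: int = 6, n_epochs: int = 500,
                 lr_initial: float = 0.5, lr_final: float = 0.01,
                 seed: int = 0):
        if rows < 2 or cols < 2:
            raise ValueError("SOM grid must be at least 2x2")
        self.rows, self.cols = rows, cols
        self.n_epochs = n_epochs
        self.lr_initial, self.lr_final = lr_initial, lr_final
        self.seed = seed
        self.weights: np.ndarray | None = None  # (rows*cols, d)
        self.qe_history: list[float] = []
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        self._grid_pos = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("descriptor matrix contains non-finite values")
        rng = np.random.default_rng(self.seed)
        lo, hi = X.min(axis=0), X.max(axis=0)
        n_units = self.rows * self.cols
        self.weights = rng.uniform(lo, hi, size=(n_units, X.shape[1]))
        radius0 = max(self.rows, self.cols) / 2.0
        self.qe_history = []
        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            lr = self.lr_initial + (self.lr_final - self.lr_initial) * frac
            radius = max(radius0 * (1.0 - frac), 0.5)
            order = rng.permutation(len(X))
            for i in order:
                x = X[i]
                bmu = np.argmin(((self.weights - x) ** 2).sum(axis=1))
                d2 = ((self._grid_pos - self._grid_pos[bmu]) ** 2).sum(axis=1)
                h = lr * np.exp(-d2 / (2.0 * radius * radius))
                self.weights += h[:, None] * (x - self.weights)
            self.qe_history.append(self.quantization_error(X))
        return self

    def best_matching_units(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) array of (row, col) BMU coordinates."""
        if self.weights is None:
            raise RuntimeError("SOM not trained")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        flat = d2.argmin(axis=1)
        return np.column_stack([flat // self.cols, flat % self.cols])

    def quantization_error(self, X: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min(axis=1)).mean())


def split_dataset(ids: list[str], bmus: np.ndarray, ratio: float = 4.0,
                  seed: int = 0, min_test: int = 5) -> list[SplitAssignment]:
    """Assign training/test roles neuron by neuron.

    Each occupied neuron sends ``floor(occupancy/(ratio+1))`` seeded-random
    molecules to the test set; any deficit relative to the global target
    ``round(n/(ratio+1))`` is drawn from the most populous neurons (which
    always retain at least one training molecule), so the test fraction
    stays within five percentage points of ``1/(ratio+1)``.
    """
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    n = len(ids)
    denom = ratio + 1.0
    target = int(round(n / denom))
    if target < min_test:
        raise ValueError(
            f"dataset of {n} cannot yield a test set of >= {min_test} at ratio {ratio}"
        )
    rng = np.random.default_rng(seed)
    neurons: dict[tuple[int, int], list[int]] = {}
    for i, (r, c) in enumerate(np.asarray(bmus, dtype=int)):
        neurons.setdefault((int(r), int(c)), []).append(i)

    test_idx: set[int] = set()
    train_count: dict[tuple[int, int], int] = {}
    for key in sorted(neurons):
        members = neurons[key]
        k = int(len(members) // denom)
        chosen = rng.choice(members, size=k, replace=False) if k else []
        test_idx.update(int(c) for c in chosen)
        train_count[key] = len(members) - k

    while len(test_idx) < target:
        # take one more from the neuron with the most remaining training members
        key = max(sorted(neurons), key=lambda k: train_count[k])
        if train_count[key] <= 1:
            break
        pool = [i for i in neurons[key] if i not in test_idx]
        test_idx.add(int(rng.choice(pool)))
        train_count[key] -= 1

    out = [
        SplitAssignment(ids[i], (int(bmus[i, 0]), int(bmus[i, 1])),
                        "test" if i in test_idx else "training")
        for i in range(n)
    ]
    if sum(1 for a in out if a.role == "test") < min_test:
        raise ValueError("could not satisfy the minimum test-set size")
    return out


def occupancy_map(assignments: list[SplitAssignment], rows: int, cols: int) -> str:
    """Text rendering of per-neuron occupancy as 'training/test' counts."""
    grid = [[(0, 0)] * cols for _ in range(rows)]
    for a in assignments:
        r, c = a.neuron
        tr, te = grid[r][c]
        grid[r][c] = (tr + (a.role == "training"), te + (a.role == "test"))
    lines = []
    for r in range(rows):
        lines.append(" ".join(f"{tr:>3d}/{te:<3d}" for tr, te in grid[r]))
    return "\n".join(lines)


def assignments_to_frame(assignments: list[SplitAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [a.molecule_id for a in assignments],
            "neuron_row": [a.neuron[0] for a in assignments],
            "neuron_col": [a.neuron[1] for a in assignments],
            "role": [a.role for a in assignments],
        }
    )
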