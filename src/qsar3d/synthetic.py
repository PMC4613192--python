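"""Synthetic inputs for every pipeline stage.

The generator emulates a congeneric medicinal-chemistry series: a rigid
2-thioimidazole scaffold (4-pyridinyl + phenyl decorated imidazole-2-thiol,
the core of classic p38/TNF-α inhibitor chemistry) decorated with
substituent pools that span size and polarity, so steric, electrostatic
and hydrophobic field blocks all carry variance.  Activities are planted
as a linear function of the molecules' own grid-field descriptor columns
plus Gaussian noise; the planted weight vector is constructed in the row
space of the descriptor matrix (a fixed combination of its leading right-
singular directions), which makes it exactly identifiable — at zero noise
a full-rank PLS fit must recover it.  Toy pharmacophore point sets with
known geometry exercise clique detection and distance-geometry embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from rdkit import Chem

from . import fields as field_mod
from .align import align_to_template
from .chem import ActivityRecord, Molecule, assign_charges, compute_clogp, \
    smiles_to_molecule
from .fields import DescriptorMatrix, FieldGrid, ProbeSpec, \
    assemble_descriptor_matrix, comfa_blocks, comsia_blocks
from .pharm import FEATURE_KINDS, PharmFeature, reference_distance_matrix, \
    embed_distance_matrix

__all__ = ["SyntheticSpec", "SyntheticSeries", "generate_molecules",
           "generate_series", "generate_pharm_toy"]

# 2-thioimidazole core: imidazole bearing 4-pyridinyl and phenyl rings,
# sulfur at C2.  {r1} decorates the sulfur (attachment through the
# fragment's last-written atom); {r2} sits para on the phenyl ring.
SCAFFOLD_CORE = "c1nc(-c2ccncc2)c(-c2ccc{r2}cc2)[nH]1"
DEFAULT_R1_POOL = (
    "C", "CC", "CCC", "CCCC", "CC(C)C", "OCC", "OCCC", "NCC",
    "FC(F)(F)C", "c1ccccc1C", "COCC", "C(=O)(O)CC",
)
DEFAULT_R2_POOL = (
    "", "(C)", "(CC)", "(O)", "(OC)", "(N)", "(F)", "(Cl)",
    "(C(F)(F)F)", "(C#N)", "(OCC)", "(C(C)C)", "(S)", "(C=O)",
)

# conventional minimum-sigma column filters
COMFA_SIGMA_DEFAULT = 2.0   # kcal/mol
COMSIA_SIGMA_DEFAULT = 0.01


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic congeneric series."""

    n_molecules: int = 30
    scaffold: str = SCAFFOLD_CORE
    r1_pool: tuple[str, ...] = DEFAULT_R1_POOL
    r2_pool: tuple[str, ...] = DEFAULT_R2_POOL
    signal_std: float = 0.7        # std of the noiseless planted pIC50 signal
    noise_sigma: float = 0.0       # Gaussian noise, pIC50 log units
    baseline_pic50: float = 6.0
    field_kind: str = "comfa"      # comfa | comsia
    include_clogp: bool = False
    spacing: float = 2.0           # Å
    margin: float = 4.0            # Å
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 10:
            raise ValueError("n_molecules must be at least 10")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not self.r1_pool or not self.r2_pool:
            raise ValueError("substituent pools must be non-empty")


@dataclass
class SyntheticSeries:
    molecules: list[Molecule]
    activities: list[ActivityRecord]
    descriptors: DescriptorMatrix
    true_weights: np.ndarray       # planted coefficients, one per column
    y_true: np.ndarray             # noiseless pIC50
    template_id: str
    grid: FieldGrid


def _series_smiles(spec: SyntheticSpec) -> list[str]:
    combos = [(r1, r2) for r1 in spec.r1_pool for r2 in spec.r2_pool]
    if spec.n_molecules > len(combos):
        raise ValueError(
            f"substituent pools give only {len(combos)} distinct molecules"
        )
    rng = np.random.default_rng(spec.seed)
    picks = rng.choice(len(combos), size=spec.n_molecules, replace=False)
    out = []
    for k in picks:
        r1, r2 = combos[k]
        out.append(r1 + "S" + spec.scaffold.format(r2=r2))
    return out


def generate_molecules(spec: SyntheticSpec, embed3d: bool = True
                       ) -> list[Molecule]:
    """Scaffold-sharing molecules with charges and clogp assigned.

    With ``embed3d`` each molecule gets one deterministic seeded ETKDG
    conformer; without, only the molecular graph is built (enough for
    descriptor-based splitting).
    """
    mols = []
    for i, smi in enumerate(_series_smiles(spec)):
        mol_id = f"syn{i:03d}"
        if embed3d:
            try:
                mol = smiles_to_molecule(smi, mol_id, seed=spec.seed * 1000 + i)
            except ValueError as exc:
                raise ValueError(f"invalid substituent chemistry: {smi!r}") from exc
        else:
            rd = Chem.MolFromSmiles(smi)
            if rd is None:
                raise ValueError(f"invalid substituent chemistry: {smi!r}")
            rd = Chem.AddHs(rd)
            rd.SetProp("_Name", mol_id)
            mol = Molecule(id=mol_id, rdmol=rd)
        assign_charges(mol)
        compute_clogp(mol)
        mols.append(mol)
    return mols


def generate_series(spec: SyntheticSpec) -> SyntheticSeries:
    """Full synthetic study: molecules, aligned fields, planted activities.

    The pipeline runs exactly as it would on real data — scaffold
    alignment onto the first molecule, shared grid, field blocks, variance
    filter and block scaling — then plants y = X·w + ε with w a fixed
    deterministic combination of the three leading right-singular vectors
    of X (scaled so the noiseless signal has std ``signal_std``).
    """
    mols = generate_molecules(spec, embed3d=True)
    template = mols[0]
    core_query = Chem.MolFromSmarts(
        Chem.MolToSmarts(Chem.MolFromSmiles(spec.scaffold.format(r2="")))
    )
    align_to_template(template, mols, query=core_query)

    probe = ProbeSpec()
    grid = field_mod.build_grid(mols, spacing=spec.spacing, margin=spec.margin)
    if spec.field_kind == "comfa":
        blocks = comfa_blocks(mols, grid, probe)
        sigma = {name: COMFA_SIGMA_DEFAULT for name in blocks}
    elif spec.field_kind == "comsia":
        blocks = comsia_blocks(mols, grid, probe)
        sigma = {name: COMSIA_SIGMA_DEFAULT for name in blocks}
    else:
        raise ValueError(f"unknown field kind {spec.field_kind!r}")
    clogp = np.array([m.properties["clogp"] for m in mols]) \
        if spec.include_clogp else None
    dm = assemble_descriptor_matrix(blocks, grid, clogp=clogp,
                                    sigma_threshold=sigma)

    Xc = dm.X - dm.X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(3, (s > 1e-10 * s[0]).sum())
    mix = np.array([1.0, 0.5, 0.25])[:k]
    w = Vt[:k].T @ (mix / s[:k])
    signal = Xc @ w
    w *= spec.signal_std / signal.std()
    y_true = spec.baseline_pic50 + Xc @ w
    rng = np.random.default_rng(spec.seed + 1)
    y = y_true + rng.normal(0.0, spec.noise_sigma, size=len(mols))
    activities = [ActivityRecord(m.id, pic50=float(v))
                  for m, v in zip(mols, y)]
    return SyntheticSeries(mols, activities, dm, w, y_true, template.id, grid)


def generate_pharm_toy(n_features: int = 6, jitter: float = 0.0,
                       n_molecules: int = 5, seed: int = 0,
                       geometry: str = "random"
                       ) -> tuple[list[PharmFeature],
                                  list[list[list[PharmFeature]]],
                                  list[int]]:
    """Reference feature configuration plus jittered rigid copies.

    ``geometry='reference'`` uses the bundled six-point pharmacophore
    geometry (embedded from its distance matrix); ``'random'`` draws
    well-separated seeded points.  Returns (reference features, per-
    molecule per-conformer feature lists, true clique as reference
    indices).  Copies are rigid motions of the reference with optional
    Gaussian positional jitter of scale ``jitter`` Å.
    """
    if n_features < 3:
        raise ValueError("need at least 3 features")
    rng = np.random.default_rng(seed)
    if geometry == "reference":
        names, D = reference_distance_matrix()
        pos = embed_distance_matrix(D).coordinates
        kinds = ["DS", "DA", "AR", "AR", "AA", "DS"]
        n_features = len(names)
    elif geometry == "random":
        pos = rng.uniform(-6.0, 6.0, size=(n_features, 3))
        # enforce minimum separation so tolerance tests are unambiguous
        for _ in range(200):
            d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(d.argmin(), d.shape)
            if d[i, j] >= 2.5:
                break
            pos[i] += rng.normal(0, 1.0, 3)
        kinds = [FEATURE_KINDS[k % len(FEATURE_KINDS)] for k in range(n_features)]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    reference = [PharmFeature(k, tuple(p)) for k, p in zip(kinds, pos)]

    others: list[list[list[PharmFeature]]] = []
    for _ in range(n_molecules - 1):
        # random proper rotation via QR with positive-determinant fix
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        t = rng.uniform(-10, 10, 3)
        moved = pos @ Q.T + t + rng.normal(0.0, jitter, size=pos.shape)
        others.append([[PharmFeature(k, tuple(p))
                        for k, p in zip(kinds, moved)]])
    return reference, others, list(range(n_features))
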