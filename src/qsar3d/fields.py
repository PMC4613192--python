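"""CoMFA and CoMSIA molecular interaction fields on a shared lattice.

CoMFA places a charged sp3-carbon probe at every point of a rectilinear
grid around the aligned series and records the Lennard-Jones 6-12 (steric)
and Coulomb (electrostatic, distance-dependent dielectric ε(r)=r)
interaction energies, clipped at ±30 kcal/mol.  CoMSIA replaces hard
potentials with Gaussian-attenuated similarity indices

    A_k(q, j) = − Σ_i  ω_probe,k · ω_ik · exp(−α · r_iq²),   α = 0.3 Å⁻²

for steric, electrostatic, hydrophobic and hydrogen-bond donor/acceptor
properties.  The per-point values over the series become the descriptor
columns of the QSAR matrix, after low-variance filtering and block scaling
so that each field contributes equal total variance (the CoMFA-standard
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule

__all__ = [
    "ProbeSpec",
    "FieldGrid",
    "ColumnInfo",
    "DescriptorMatrix",
    "build_grid",
    "comfa_steric",
    "comfa_electrostatic",
    "comsia_field",
    "assign_property_weights",
    "comfa_blocks",
    "comsia_blocks",
    "assemble_descriptor_matrix",
    "VDW_PARAMS",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.0  # kcal·Å/(mol·e²)
COMSIA_PROPERTIES = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")

# Generic element-keyed van der Waals parameters (radius Å, well depth
# kcal/mol): Bondi-style radii with UFF-like well depths.  Good enough for
# property-based field analysis; not a force field.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.030),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.200),
    "S": (1.80, 0.274),
    "Cl": (1.75, 0.240),
    "Br": (1.85, 0.320),
    "I": (1.98, 0.350),
}


@dataclass(frozen=True)
class ProbeSpec:
    """The common CoMFA/CoMSIA probe: an sp3 carbon bearing +1 e charge and
    unit similarity weights, with Gaussian attenuation α = 0.3 Å⁻²."""

    element: str = "C"
    charge: float = 1.0
    radius: float = 1.0
    steric: float = 1.0
    hydrophobic: float = 1.0
    donor: float = 1.0
    acceptor: float = 1.0
    alpha: float = 0.3

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("attenuation factor alpha must be positive")

    def weight(self, prop: str) -> float:
        return {
            "steric": self.steric,
            "electrostatic": self.charge,
            "hydrophobic": self.hydrophobic,
            "donor": self.donor,
            "acceptor": self.acceptor,
        }[prop]


@dataclass
class FieldGrid:
    """Shared rectilinear lattice.  Points iterate z-fastest (x slow, y,
    then z), matching the OpenDX convention used for export."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])
        return self.origin[None, :] + idx * self.spacing

    def point(self, flat_index: int) -> np.ndarray:
        nx, ny, nz = self.dims
        ix, rem = divmod(flat_index, ny * nz)
        iy, iz = divmod(rem, nz)
        return self.origin + np.array([ix, iy, iz]) * self.spacing


@dataclass(frozen=True)
class ColumnInfo:
    """Maps a descriptor column back to its field block and lattice point
    (lattice_index is -1 for whole-molecule columns such as clogp)."""

    field: str
    lattice_index: int


@dataclass
class DescriptorMatrix:
    X: np.ndarray
    columns: list[ColumnInfo]
    grid: FieldGrid
    block_scales: dict[str, float] = field(default_factory=dict)

    @property
    def field_names(self) -> list[str]:
        seen = []
        for c in self.columns:
            if c.field not in seen:
                seen.append(c.field)
        return seen


def build_grid(mols: list[Molecule], spacing: float = 2.0, margin: float = 4.0,
               conformers: list[int] | None = None) -> FieldGrid:
    """Smallest lattice enclosing every molecule with ≥ ``margin`` Å on all
    six faces.  Deterministic for a fixed molecule set (no global snapping,
    so translating the whole series translates the grid with it)."""
    if not mols:
        raise ValueError("empty molecule list")
    confs = conformers or [m.n_conformers - 1 for m in mols]
    all_xyz = np.vstack([m.coords(c) for m, c in zip(mols, confs)])
    lo = all_xyz.min(axis=0) - margin
    hi = all_xyz.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return FieldGrid(origin=lo, spacing=float(spacing), dims=dims)


def _vdw_params(mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
    radii, eps = [], []
    for sym in mol.elements:
        if sym not in VDW_PARAMS:
            raise ValueError(f"{mol.id}: no van der Waals parameters for {sym}")
        r, e = VDW_PARAMS[sym]
        radii.append(r)
        eps.append(e)
    return np.array(radii), np.array(eps)


def _distances(mol: Molecule, grid: FieldGrid, conformer: int) -> np.ndarray:
    pts = grid.points()
    xyz = mol.coords(conformer)
    return np.sqrt(((pts[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2))


def comfa_steric(mol: Molecule, grid: FieldGrid, probe: ProbeSpec = ProbeSpec(),
                 conformer: int = 0, cutoff: float = 30.0) -> np.ndarray:
    """Lennard-Jones 6-12 probe-atom energy sum per lattice point (kcal/mol),
    clipped to ±``cutoff``."""
    radii, eps = _vdw_params(mol)
    probe_r, probe_e = VDW_PARAMS[probe.element]
    r = np.maximum(_distances(mol, grid, conformer), 1e-6)
    r0 = radii + probe_r
    e_ij = np.sqrt(eps * probe_e)
    frac6 = (r0[None, :] / r) ** 6
    with np.errstate(over="ignore"):
        energy = (e_ij[None, :] * (frac6 ** 2 - 2.0 * frac6)).sum(axis=1)
    return np.clip(energy, -cutoff, cutoff)


def comfa_electrostatic(mol: Molecule, grid: FieldGrid,
                        probe: ProbeSpec = ProbeSpec(), conformer: int = 0,
                        cutoff: float = 30.0) -> np.ndarray:
    """Coulomb probe-atom energy with distance-dependent dielectric ε(r)=r,
    i.e. 332·q_i·q_probe/r² summed over atoms, clipped to ±``cutoff``.

    The CoMFA convention of replacing values at sterically excluded points
    by the column mean is applied at matrix assembly (`comfa_blocks`),
    where all molecules are known.
    """
    q = mol.charges
    if q is None:
        raise ValueError(f"{mol.id}: assign partial charges first")
    if np.allclose(q, 0.0):
        warnings.warn(f"{mol.id}: all partial charges are zero", stacklevel=2)
        return np.zeros(grid.n_points)
    r = np.maximum(_distances(mol, grid, conformer), 1e-6)
    energy = (COULOMB_CONSTANT * probe.charge * q[None, :] / r ** 2).sum(axis=1)
    return np.clip(energy, -cutoff, cutoff)


def assign_property_weights(mol: Molecule, prop: str) -> np.ndarray:
    """Per-atom CoMSIA physicochemical weights ω_ik.

    steric: r_vdW³ (volume proxy); electrostatic: PEOE partial charge;
    hydrophobic: Crippen per-atom logP contribution; donor/acceptor: 0/1
    pharmacophore typing (untyped atoms default to 0).
    """
    rd = mol.rdmol
    n = rd.GetNumAtoms()
    if prop == "steric":
        radii, _ = _vdw_params(mol)
        return radii ** 3
    if prop == "electrostatic":
        q = mol.charges
        if q is None:
            raise ValueError(f"{mol.id}: assign partial charges first")
        return q.copy()
    if prop == "hydrophobic":
        from rdkit.Chem import rdMolDescriptors
        contribs = rdMolDescriptors._CalcCrippenContribs(rd)
        return np.array([c[0] for c in contribs])
    if prop == "donor":
        w = np.zeros(n)
        for a in rd.GetAtoms():
            if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs(includeNeighbors=True) > 0:
                w[a.GetIdx()] = 1.0
        return w
    if prop == "acceptor":
        w = np.zeros(n)
        for a in rd.GetAtoms():
            sym = a.GetSymbol()
            if a.GetFormalCharge() > 0:
                continue
            if sym == "O":
                w[a.GetIdx()] = 1.0
            elif sym == "N" and a.GetTotalNumHs(includeNeighbors=True) == 0:
                # exclude substituted pyrrole-type N (aromatic, 3 neighbors)
                if not (a.GetIsAromatic() and a.GetDegree() == 3):
                    w[a.GetIdx()] = 1.0
        return w
    raise ValueError(f"unknown CoMSIA property {prop!r}")


def comsia_field(mol: Molecule, grid: FieldGrid, probe: ProbeSpec = ProbeSpec(),
                 prop: str = "steric", conformer: int = 0,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Gaussian similarity index −Σ_i ω_probe·ω_i·exp(−α r²) per lattice
    point (unitless, finite everywhere)."""
    if prop not in COMSIA_PROPERTIES:
        raise ValueError(f"unknown CoMSIA property {prop!r}")
    w = assign_property_weights(mol, prop) if weights is None else np.asarray(weights, float)
    r2 = _distances(mol, grid, conformer) ** 2
    return -(probe.weight(prop) * w[None, :] * np.exp(-probe.alpha * r2)).sum(axis=1)


def comfa_blocks(mols: list[Molecule], grid: FieldGrid,
                 probe: ProbeSpec = ProbeSpec(),
                 conformers: list[int] | None = None,
                 cutoff: float = 30.0) -> dict[str, np.ndarray]:
    """Per-field (n_molecules × n_points) CoMFA value blocks.

    At lattice points where a molecule's steric energy sits at the +cutoff
    (i.e. inside the molecule), its electrostatic value is replaced by the
    column mean over the remaining molecules — the standard convention that
    stops meaningless in-body Coulomb values from dominating the column.
    """
    confs = conformers or [m.n_conformers - 1 for m in mols]
    steric = np.vstack([comfa_steric(m, grid, probe, c, cutoff)
                        for m, c in zip(mols, confs)])
    elec = np.vstack([comfa_electrostatic(m, grid, probe, c, cutoff)
                      for m, c in zip(mols, confs)])
    excluded = steric >= cutoff
    ok = ~excluded
    col_sum = np.where(ok, elec, 0.0).sum(axis=0)
    col_n = ok.sum(axis=0)
    col_mean = np.divide(col_sum, col_n, out=np.zeros_like(col_sum),
                         where=col_n > 0)
    elec = np.where(excluded, col_mean[None, :], elec)
    return {"steric": steric, "electrostatic": elec}


def comsia_blocks(mols: list[Molecule], grid: FieldGrid,
                  probe: ProbeSpec = ProbeSpec(),
                  conformers: list[int] | None = None,
                  properties: tuple[str, ...] = COMSIA_PROPERTIES,
                  truncate: float | None = 0.3) -> dict[str, np.ndarray]:
    """Per-property CoMSIA blocks; values optionally clipped to ±truncate
    (one reading of the conventional 0.3 contribution cut; pass None to
    keep raw Gaussian sums)."""
    confs = conformers or [m.n_conformers - 1 for m in mols]
    out = {}
    for prop in properties:
        block = np.vstack([comsia_field(m, grid, probe, prop, c)
                           for m, c in zip(mols, confs)])
        if truncate is not None:
            block = np.clip(block, -truncate, truncate)
        out[prop] = block
    return out


def assemble_descriptor_matrix(blocks: dict[str, np.ndarray], grid: FieldGrid,
                               clogp: np.ndarray | None = None,
                               sigma_threshold: float | dict[str, float] = 0.0,
                               block_scaling: bool = True) -> DescriptorMatrix:
    """Flatten field blocks into the QSAR descriptor matrix.

    Columns with standard deviation below the (per-block) threshold are
    dropped; each surviving block is then rescaled so its total variance is
    1, giving every field equal a-priori weight (ClogP, when supplied,
    forms its own unit-variance block).  Column metadata maps every column
    back to (field, lattice index).
    """
    X_parts, columns, scales = [], [], {}
    for name in blocks:
        block = np.asarray(blocks[name], dtype=float)
        thr = sigma_threshold.get(name, 0.0) if isinstance(sigma_threshold, dict) \
            else float(sigma_threshold)
        sd = block.std(axis=0, ddof=1)
        keep = np.where(sd > max(thr, 1e-12))[0]
        if keep.size == 0:
            continue
        sub = block[:, keep]
        scale = 1.0
        if block_scaling:
            total_var = sub.var(axis=0, ddof=1).sum()
            scale = 1.0 / np.sqrt(total_var)
            sub = sub * scale
        scales[name] = scale
        X_parts.append(sub)
        columns.extend(ColumnInfo(name, int(k)) for k in keep)
    if clogp is not None:
        col = np.asarray(clogp, dtype=float)[:, None]
        sd = col.std(ddof=1)
        if sd > 1e-12:
            scale = 1.0 / sd if block_scaling else 1.0
            X_parts.append(col * scale)
            columns.append(ColumnInfo("clogp", -1))
            scales["clogp"] = scale
    if not X_parts:
        raise ValueError("no descriptor columns survived the variance filter")
    return DescriptorMatrix(np.hstack(X_parts), columns, grid, scales)
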