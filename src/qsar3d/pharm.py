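"""DISCO-style pharmacophore elucidation and distance-geometry validation.

Features (H-bond donor/acceptor atoms, projected donor/acceptor sites
3.00 Å along the idealized hydrogen-bond axis, hydrophobic and aromatic
ring centroids) are perceived per conformer.  Candidate pharmacophores are
found by maximal-clique detection in the association graph between a
reference molecule's features and every other molecule's features, under a
pairwise distance tolerance.  A published six-point pharmacophore of
pyridinylimidazole TNF-α release inhibitors is bundled as a reference
distance matrix, and a classical-scaling + least-squares embedder checks
whether any such matrix is realizable in 3D.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem
from scipy.optimize import least_squares
from scipy.sparse.csgraph import shortest_path

from .chem import Molecule
from .fields import assign_property_weights

__all__ = [
    "PharmFeature",
    "PharmModel",
    "EmbeddingResult",
    "SITE_PROJECTION_DISTANCE",
    "TNFA_PHARMACOPHORE_FEATURES",
    "TNFA_PHARMACOPHORE_DISTANCES",
    "reference_distance_matrix",
    "perceive_features",
    "generate_conformers",
    "select_diverse_conformers",
    "tanimoto_similarity",
    "clique_search",
    "score_model",
    "feature_distance_matrix",
    "embed_distance_matrix",
]

SITE_PROJECTION_DISTANCE = 3.00  # Å, donor/acceptor site offset along the H-bond axis

FEATURE_KINDS = ("DA", "AA", "DS", "AS", "HP", "AR")

# Six-point pharmacophore of pyridinylimidazole TNF-α release inhibitors:
# coincident donor/acceptor nitrogen atoms of the imidazole and pyridine
# rings (DA1/AA1, AA2/DA2), their projected receptor-side donor sites
# (DS1, DS2), and the fused hydrophobic/aromatic centers of the two rings
# (HP1/AR1, HP2/AR2).  Distances in Å with a 0.25 Å tolerance.
TNFA_PHARMACOPHORE_FEATURES = (
    "DS1", "DA1/AA1", "HP1/AR1", "HP2/AR2", "AA2/DA2", "DS2",
)
TNFA_PHARMACOPHORE_DISTANCES: dict[tuple[str, str], float] = {
    ("DS1", "DA1/AA1"): 3.00,
    ("DS1", "HP1/AR1"): 4.12,
    ("DS1", "HP2/AR2"): 7.87,
    ("DS1", "AA2/DA2"): 9.20,
    ("DS1", "DS2"): 12.16,
    ("DA1/AA1", "HP1/AR1"): 1.12,
    ("DA1/AA1", "HP2/AR2"): 5.05,
    ("DA1/AA1", "AA2/DA2"): 6.41,
    ("DA1/AA1", "DS2"): 9.41,
    ("HP1/AR1", "HP2/AR2"): 4.05,
    ("HP1/AR1", "AA2/DA2"): 5.41,
    ("HP1/AR1", "DS2"): 8.41,
    ("HP2/AR2", "AA2/DA2"): 1.37,
    ("HP2/AR2", "DS2"): 4.37,
    ("AA2/DA2", "DS2"): 3.00,
}
TNFA_PHARMACOPHORE_TOLERANCE = 0.25  # Å


def reference_distance_matrix() -> tuple[list[str], np.ndarray]:
    """The bundled six-point pharmacophore as (feature names, 6×6 matrix)."""
    names = list(TNFA_PHARMACOPHORE_FEATURES)
    n = len(names)
    D = np.zeros((n, n))
    for (a, b), d in TNFA_PHARMACOPHORE_DISTANCES.items():
        i, j = names.index(a), names.index(b)
        D[i, j] = D[j, i] = d
    return names, D


@dataclass(frozen=True)
class PharmFeature:
    kind: str                       # one of FEATURE_KINDS
    position: tuple[float, float, float]
    atoms: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class PharmModel:
    features: list[PharmFeature]    # reference configuration
    tolerance: float                # Å
    hits: int = 0
    score: float | None = None
    dmean: float | None = None
    # per matched molecule: (conformer index, list of molecule feature indices
    # aligned with ``features``); None marks an unmatched molecule
    matches: list[tuple[int, list[int]] | None] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.features)

    def distance_matrix(self) -> np.ndarray:
        return feature_distance_matrix(self)


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray | None:
    n = np.linalg.norm(v)
    return None if n < 1e-8 else v / n


def perceive_features(mol: Molecule, conformer: int = 0) -> list[PharmFeature]:
    """Deterministic pharmacophore features of one conformer.

    Donor atoms (N/O with H) give a DA plus a DS projected 3.00 Å along
    the mean N–H/O–H axis; acceptor atoms give an AA plus an AS 3.00 Å
    along the idealized lone-pair axis (opposite the mean bond vector).
    Each aromatic ring gives an AR at its centroid, plus an HP when the
    ring is carbon-dominated.  No perceivable features is not an error.
    """
    rd = mol.rdmol
    xyz = mol.coords(conformer)
    donor_w = assign_property_weights(mol, "donor")
    acceptor_w = assign_property_weights(mol, "acceptor")
    feats: list[PharmFeature] = []
    for atom in rd.GetAtoms():
        i = atom.GetIdx()
        nbr_pos = [xyz[n.GetIdx()] for n in atom.GetNeighbors()]
        h_pos = [xyz[n.GetIdx()] for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        if donor_w[i] > 0:
            feats.append(PharmFeature("DA", tuple(xyz[i]), (i,)))
            axis = None
            if h_pos:
                axis = _unit(np.mean([h - xyz[i] for h in h_pos], axis=0))
            if axis is None and nbr_pos:
                axis = _unit(-np.mean([p - xyz[i] for p in nbr_pos], axis=0))
            if axis is not None:
                site = xyz[i] + SITE_PROJECTION_DISTANCE * axis
                feats.append(PharmFeature("DS", tuple(site), (i,)))
        if acceptor_w[i] > 0:
            feats.append(PharmFeature("AA", tuple(xyz[i]), (i,)))
            axis = _unit(-np.mean([p - xyz[i] for p in nbr_pos], axis=0)) \
                if nbr_pos else None
            if axis is not None:
                site = xyz[i] + SITE_PROJECTION_DISTANCE * axis
                feats.append(PharmFeature("AS", tuple(site), (i,)))
    for ring in rd.GetRingInfo().AtomRings():
        if not all(rd.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            continue
        centroid = xyz[list(ring)].mean(axis=0)
        feats.append(PharmFeature("AR", tuple(centroid), tuple(sorted(ring))))
        n_carbon = sum(rd.GetAtomWithIdx(a).GetAtomicNum() == 6 for a in ring)
        if n_carbon * 2 > len(ring):
            feats.append(PharmFeature("HP", tuple(centroid), tuple(sorted(ring))))
    return feats


# ---------------------------------------------------------------------------
# conformers
# ---------------------------------------------------------------------------

def generate_conformers(mol: Molecule, n_conformers: int = 50,
                        seed: int = 0) -> list[int]:
    """Seeded multi-conformer embedding (ETKDG); returns conformer ids."""
    params = AllChem.ETKDGv3()
    params.randomSeed = seed & 0x7FFFFFFF
    params.clearConfs = False
    ids = AllChem.EmbedMultipleConfs(mol.rdmol, numConfs=n_conformers, params=params)
    return list(ids)


def select_diverse_conformers(mol: Molecule, conf_ids: list[int],
                              k: int = 7) -> list[int]:
    """Maximin RMSD-diversity subset of conformers (deterministic: starts
    from the first id, then repeatedly adds the conformer farthest from the
    chosen set)."""
    if len(conf_ids) <= k:
        return list(conf_ids)
    coords = {c: mol.coords(c)[mol.heavy_atom_indices()] for c in conf_ids}

    def rmsd(a, b):
        d = coords[a] - coords[b]
        return float(np.sqrt((d ** 2).sum() / len(d)))

    chosen = [conf_ids[0]]
    remaining = list(conf_ids[1:])
    while len(chosen) < k:
        best = max(remaining, key=lambda c: min(rmsd(c, s) for s in chosen))
        chosen.append(best)
        remaining.remove(best)
    return chosen


def tanimoto_similarity(a: Molecule, b: Molecule, radius: int = 2) -> float:
    """Morgan-fingerprint Tanimoto similarity between two molecules."""
    fa = AllChem.GetMorganFingerprintAsBitVect(Chem.RemoveHs(a.rdmol), radius)
    fb = AllChem.GetMorganFingerprintAsBitVect(Chem.RemoveHs(b.rdmol), radius)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


# ---------------------------------------------------------------------------
# clique detection
# ---------------------------------------------------------------------------

def _pairwise(feats: list[PharmFeature]) -> np.ndarray:
    pos = np.array([f.xyz for f in feats]) if feats else np.zeros((0, 3))
    return np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))


def _conformer_cliques(ref_feats, ref_D, mol_feats, tolerance, max_size):
    """Maximal cliques of the reference/molecule association graph, as
    (ref index tuple, mol index tuple) pairs."""
    mol_D = _pairwise(mol_feats)
    nodes = [(i, j) for i, rf in enumerate(ref_feats)
             for j, mf in enumerate(mol_feats) if rf.kind == mf.kind]
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for (i1, j1), (i2, j2) in itertools.combinations(nodes, 2):
        if i1 == i2 or j1 == j2:
            continue
        if abs(ref_D[i1, i2] - mol_D[j1, j2]) <= tolerance:
            G.add_edge((i1, j1), (i2, j2))
    out = []
    for clique in nx.find_cliques(G):
        clique = sorted(clique)
        ref_idx = tuple(i for i, _ in clique)
        mol_idx = tuple(j for _, j in clique)
        if len(set(ref_idx)) == len(ref_idx) and len(set(mol_idx)) == len(mol_idx):
            out.append((ref_idx, mol_idx))
    return out


def clique_search(reference: list[PharmFeature],
                  others: list[list[list[PharmFeature]]],
                  tolerance: float = 0.25,
                  min_size: int = 4, max_size: int = 16,
                  min_hits: int | None = None) -> list[PharmModel]:
    """Pharmacophore hypotheses common to the reference and the other
    molecules.

    ``others`` holds, per molecule, per conformer, a feature list.  For
    every conformer an association graph is built between reference and
    molecule features (same kind, all pairwise reference/molecule distance
    differences within ``tolerance``), and its maximal cliques enumerated.
    A candidate model — a subset of reference features — is emitted when at
    least ``min_hits`` molecules (default: all, the reference included)
    match it with a size in [min_size, max_size].  Models are ranked by
    score (descending), then size, then tolerance.
    """
    if min_size > max_size:
        raise ValueError("min_size exceeds max_size")
    if not reference:
        raise ValueError("reference feature list is empty")
    n_molecules = len(others) + 1
    if min_hits is None:
        min_hits = n_molecules
    ref_D = _pairwise(reference)

    # per molecule: ref-subset -> best (deviation, conformer, mol indices)
    supports: list[dict[tuple[int, ...], tuple[float, int, tuple[int, ...]]]] = []
    candidates: set[tuple[int, ...]] = set()
    for mol_feats_per_conf in others:
        support: dict[tuple[int, ...], tuple[float, int, tuple[int, ...]]] = {}
        for conf_idx, mol_feats in enumerate(mol_feats_per_conf):
            for ref_idx, mol_idx in _conformer_cliques(
                    reference, ref_D, mol_feats, tolerance, max_size):
                if len(ref_idx) < 2:
                    continue
                mol_D = _pairwise(mol_feats)
                devs = [abs(ref_D[a, b] - mol_D[c, d])
                        for (a, c), (b, d) in itertools.combinations(
                            zip(ref_idx, mol_idx), 2)]
                dev = float(np.mean(devs)) if devs else 0.0
                key = ref_idx
                if key not in support or dev < support[key][0]:
                    support[key] = (dev, conf_idx, mol_idx)
                candidates.add(key)
        supports.append(support)

    def molecule_match(support, subset):
        """Best sub-match of ``subset`` within any supported clique."""
        best = None
        sub = set(subset)
        for key, (dev, conf, mol_idx) in support.items():
            if sub <= set(key):
                sel = [mol_idx[key.index(i)] for i in subset]
                if best is None or dev < best[0]:
                    best = (dev, conf, sel)
        return best

    # close candidates under pairwise intersection: a model common to
    # several molecules is an intersection of their (maximal) cliques and
    # need not itself be a maximal clique of any single molecule
    closure = {frozenset(c) for c in candidates}
    frontier = set(closure)
    while frontier:
        new = set()
        for a in frontier:
            for b in closure:
                c = a & b
                if len(c) >= min_size and c not in closure:
                    new.add(c)
        closure |= new
        frontier = new

    # a clique larger than max_size still supports all its max_size subsets
    expanded = set(closure)
    for c in closure:
        if len(c) > max_size:
            expanded |= {frozenset(s)
                         for s in itertools.combinations(sorted(c), max_size)}

    qualifying: dict[frozenset, tuple[int, list]] = {}
    for subset_fs in expanded:
        subset = tuple(sorted(subset_fs))
        if not (min_size <= len(subset) <= max_size):
            continue
        matches: list[tuple[int, list[int]] | None] = []
        hits = 1  # the reference matches itself
        for support in supports:
            m = molecule_match(support, subset)
            if m is None:
                matches.append(None)
            else:
                matches.append((m[1], list(m[2])))
                hits += 1
        if hits >= min_hits:
            qualifying[subset_fs] = (hits, matches)

    models = []
    for subset_fs, (hits, matches) in qualifying.items():
        if any(other > subset_fs for other in qualifying):
            continue  # emit only maximal qualifying models
        subset = tuple(sorted(subset_fs))
        model = PharmModel([reference[i] for i in subset], tolerance,
                           hits=hits, matches=matches)
        score_model(model, others)
        models.append(model)
    models.sort(key=lambda m: (-(m.score or 0), -m.size, m.tolerance))
    return models


def score_model(model: PharmModel,
                others: list[list[list[PharmFeature]]]) -> tuple[float, float]:
    """Overlap score and mean inter-feature distance of a model.

    score = SIZE·(1 − mean pairwise-distance deviation / tolerance),
    averaged over matched molecules (the reference counts with deviation
    0); dmean = mean over matched conformers of the mean pairwise matched-
    feature distance.  Both are documented stand-ins for the proprietary
    originals.
    """
    if model.hits < 1:
        raise ValueError("model has no matches")
    ref_D = model.distance_matrix()
    iu = np.triu_indices(model.size, k=1)
    scores = [float(model.size)]           # reference molecule, zero deviation
    dmeans = [float(ref_D[iu].mean())] if iu[0].size else [0.0]
    for mol_idx, match in enumerate(model.matches or []):
        if match is None:
            continue
        conf, feat_idx = match
        feats = others[mol_idx][conf]
        pos = np.array([feats[j].xyz for j in feat_idx])
        D = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
        dev = float(np.abs(D[iu] - ref_D[iu]).mean()) if iu[0].size else 0.0
        scores.append(model.size * (1.0 - dev / model.tolerance))
        dmeans.append(float(D[iu].mean()) if iu[0].size else 0.0)
    model.score = float(np.mean(scores))
    model.dmean = float(np.mean(dmeans))
    return model.score, model.dmean


def feature_distance_matrix(model: PharmModel) -> np.ndarray:
    """Symmetric Euclidean distance matrix (Å) of the model's reference
    feature configuration."""
    return _pairwise(model.features)


# ---------------------------------------------------------------------------
# distance geometry
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    coordinates: np.ndarray           # (n, 3), up to rigid motion
    residuals: np.ndarray             # signed residual per retained pair (n, n)
    max_residual: float
    predicted_distance: float | None  # realized distance of the left-out pair


def embed_distance_matrix(D: np.ndarray, dim: int = 3,
                          leave_out: tuple[int, int] | None = None,
                          max_nfev: int = 10000,
                          max_allowed_residual: float = 1.0) -> EmbeddingResult:
    """Embed a distance matrix in ``dim`` dimensions.

    Classical metric scaling on the (shortest-path-completed) matrix gives
    starting coordinates, refined by least squares over all retained pairs.
    With ``leave_out`` the named pair is excluded from both stages and its
    realized (predicted) distance is reported.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 0:
        raise ValueError("D must be symmetric with zero diagonal")
    mask = ~np.eye(n, dtype=bool)
    if leave_out is not None:
        i, j = leave_out
        mask[i, j] = mask[j, i] = False
    # complete missing entries along shortest paths, then double-center
    graph = np.where(mask, D, 0.0)
    Dfull = np.where(mask, D, shortest_path(graph, method="D", directed=False))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dfull ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    X0 = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if mask[i, j]]

    def residual_vec(x):
        X = x.reshape(n, dim)
        return np.array([np.linalg.norm(X[i] - X[j]) - D[i, j] for i, j in pairs])

    sol = least_squares(residual_vec, X0.ravel(), xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=max_nfev)
    res_vec = residual_vec(sol.x)
    if not np.isfinite(res_vec).all():
        raise ValueError("distance-geometry refinement diverged")
    X = sol.x.reshape(n, dim)
    residuals = np.zeros((n, n))
    for (i, j), r in zip(pairs, res_vec):
        residuals[i, j] = residuals[j, i] = r
    predicted = None
    if leave_out is not None:
        i, j = leave_out
        predicted = float(np.linalg.norm(X[i] - X[j]))
    max_res = float(np.abs(res_vec).max()) if len(res_vec) else 0.0
    if max_res > max_allowed_residual:
        raise ValueError(
            f"distance matrix not embeddable in {dim}D (max residual {max_res:.3f} Å)"
        )
    return EmbeddingResult(X, residuals, max_res, predicted)
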