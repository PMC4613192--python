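"""Independent reference implementations used only as test oracles.

Each function here deliberately takes a different algorithmic route from
the package code it checks (SIMPLS vs NIPALS, explicit refits vs the
package's cross-validation loop, exhaustive enumeration vs clique
detection), so agreement is evidence of correctness rather than repetition.
"""

from itertools import combinations, permutations, product

import networkx as nx
import numpy as np


def simpls_coefficients(X: np.ndarray, y: np.ndarray, n_components: int
                        ) -> tuple[np.ndarray, float]:
    """SIMPLS (de Jong) PLS1 regression; returns (coefficients, intercept)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    s = Xc.T @ yc
    R, V, q = [], [], []
    for _ in range(n_components):
        r = s.copy()
        t = Xc @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-14:
            break
        t /= normt
        r /= normt
        p = Xc.T @ t
        q.append(float(yc @ t))
        v = p.copy()
        for vj in V:
            v -= (vj @ p) * vj
        nv = np.linalg.norm(v)
        if nv < 1e-14:
            break
        v /= nv
        V.append(v)
        s = s - v * (v @ s)
        R.append(r)
    b = np.zeros(X.shape[1])
    for rk, qk in zip(R, q):
        b += qk * rk
    return b, float(ym - xm @ b)


def brute_force_loo(model_cls, X: np.ndarray, y: np.ndarray, c_max: int):
    """Explicit n-refit leave-one-out: for each c, refit on every n−1
    subset via the public fit() and accumulate PRESS/SD independently."""
    n = len(y)
    press = np.zeros(c_max)
    sd = 0.0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        sd += (y[i] - y[mask].mean()) ** 2
        for c in range(1, c_max + 1):
            res = model_cls(y[mask], X[mask]).fit(c)
            press[c - 1] += (y[i] - res.predict(X[i])[0]) ** 2
    q2 = 1 - press / sd
    sep = np.sqrt(press / (n - np.arange(1, c_max + 1) - 1))
    return q2, sep


def max_common_subgraph_size(g1: nx.Graph, g2: nx.Graph) -> int:
    """Largest common connected node-induced subgraph (element- and
    bond-order-preserving), by exhaustive enumeration.  Small graphs only."""
    nm = nx.algorithms.isomorphism.categorical_node_match("element", None)
    em = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    small, big = sorted((g1, g2), key=lambda g: g.number_of_nodes())
    for size in range(small.number_of_nodes(), 0, -1):
        for nodes in combinations(small.nodes, size):
            sub = small.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            gm = nx.algorithms.isomorphism.GraphMatcher(
                big, sub, node_match=nm, edge_match=em)
            if gm.subgraph_is_isomorphic():
                return size
    return 0


def mol_to_graph(mol) -> nx.Graph:
    g = nx.Graph()
    rd = mol.rdmol
    for a in rd.GetAtoms():
        if a.GetAtomicNum() > 1:
            g.add_node(a.GetIdx(), element=a.GetSymbol())
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in g and j in g:
            g.add_edge(i, j, order=b.GetBondTypeAsDouble())
    return g


def _pairwise(feats):
    pos = np.array([f.xyz for f in feats])
    return np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))


def _molecule_supports(reference, subset, conformer_feature_lists, tol):
    ref_D = _pairwise(reference)
    for feats in conformer_feature_lists:
        if not feats:
            continue
        mol_D = _pairwise(feats)
        cands = [[j for j, f in enumerate(feats) if f.kind == reference[i].kind]
                 for i in subset]
        for assign in product(*cands):
            if len(set(assign)) < len(assign):
                continue
            ok = all(
                abs(ref_D[subset[a], subset[b]] - mol_D[assign[a], assign[b]]) <= tol
                for a, b in combinations(range(len(subset)), 2)
            )
            if ok:
                return True
    return False


def enumerate_pharmacophores(reference, others, tol, min_size, max_size,
                             min_hits):
    """All maximal qualifying reference-feature subsets, by brute force."""
    n = len(reference)
    qualifying = {}
    for size in range(min_size, min(max_size, n) + 1):
        for subset in combinations(range(n), size):
            hits = 1 + sum(_molecule_supports(reference, subset, confs, tol)
                           for confs in others)
            if hits >= min_hits:
                qualifying[frozenset(subset)] = hits
    return {s for s in qualifying
            if not any(t > s for t in qualifying)}
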