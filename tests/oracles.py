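"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration / numerical
integration, independent of the library's implementation paths.
"""

import itertools

import numpy as np
from rdkit import Chem


def heavy_graph(smiles: str):
    """(labels, adjacency-set) of the heavy-atom graph of a SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    labels = [a.GetSymbol() for a in mol.GetAtoms()]
    edges = set()
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.add((min(i, j), max(i, j)))
    return labels, edges


def mcs_size_bruteforce(smiles_a: str, smiles_b: str) -> int:
    """Exhaustive maximum connected common (non-induced) subgraph atom count.

    For every subset S of A's atoms (largest first) and every element-
    preserving injection f into B, the common-edge graph on S (edges of A
    within S whose images are edges of B) must be connected.
    """
    la, ea = heavy_graph(smiles_a)
    lb, eb = heavy_graph(smiles_b)
    na, nb = len(la), len(lb)
    best_possible = min(na, nb)
    for k in range(best_possible, 0, -1):
        for subset in itertools.combinations(range(na), k):
            if _has_common_mapping(subset, la, ea, lb, eb):
                return k
    return 0


def _has_common_mapping(subset, la, ea, lb, eb):
    candidates = {u: [v for v in range(len(lb)) if lb[v] == la[u]] for u in subset}
    if any(not c for c in candidates.values()):
        return False
    for images in itertools.permutations(range(len(lb)), len(subset)):
        f = dict(zip(subset, images))
        if any(la[u] != lb[f[u]] for u in subset):
            continue
        common = [
            (u, v)
            for u, v in itertools.combinations(subset, 2)
            if (min(u, v), max(u, v)) in ea
            and (min(f[u], f[v]), max(f[u], f[v])) in eb
        ]
        if _connected(subset, common):
            return True
    return False


def _connected(nodes, edges):
    nodes = list(nodes)
    if len(nodes) == 1:
        return True
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(nodes)


def gaussian_overlap_grid(xa, alpha_a, xb, alpha_b, prefactor, extent=6.0, step=0.15):
    """Numerical 3D grid integration of sum_ij ∫ rho_i rho_j d^3r."""
    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    lo = np.minimum(xa.min(axis=0), xb.min(axis=0)) - extent
    hi = np.maximum(xa.max(axis=0), xb.max(axis=0)) + extent
    axes = [np.arange(lo[d], hi[d], step) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def density(xs, alphas):
        rho = np.zeros(len(pts))
        for c, al in zip(xs, alphas):
            rho += prefactor * np.exp(-al * np.sum((pts - c) ** 2, axis=1))
        return rho

    return float(np.sum(density(xa, alpha_a) * density(xb, alpha_b)) * step**3)


def pairwise_energy_bruteforce(coords_a, elements_a, coords_b, elements_b,
                               sigma_eps, cutoff=None):
    """O(n·m) double-loop Lennard-Jones sum, Lorentz–Berthelot mixing."""
    total = 0.0
    for xa, ea in zip(coords_a, elements_a):
        for xb, eb in zip(coords_b, elements_b):
            r = float(np.linalg.norm(np.asarray(xa) - np.asarray(xb)))
            if cutoff is not None and r > cutoff:
                continue
            sa, epsa = sigma_eps(ea)
            sb, epsb = sigma_eps(eb)
            sig = 0.5 * (sa + sb)
            eps = (epsa * epsb) ** 0.5
            sr6 = (sig / r) ** 6
            total += 4 * eps * (sr6**2 - sr6)
    return total


def contact_counts_bruteforce(prot_elements, prot_coords, prot_eligible,
                              lig_elements, lig_coords, lig_eligible, cutoff):
    """Double-loop contact classification (CC / NN / OO / XX)."""
    cc = nn = oo = xx = 0
    for i, (ea, xa) in enumerate(zip(prot_elements, prot_coords)):
        if not prot_eligible[i]:
            continue
        for j, (eb, xb) in enumerate(zip(lig_elements, lig_coords)):
            if not lig_eligible[j]:
                continue
            if np.linalg.norm(np.asarray(xa) - np.asarray(xb)) > cutoff:
                continue
            if ea == eb == "C":
                cc += 1
            elif ea == eb == "N":
                nn += 1
            elif ea == eb == "O":
                oo += 1
            else:
                xx += 1
    return cc, nn, oo, xx


def best_rotation_rmsd_oracle(mobile, target, n_rotations=10000, seed=0):
    """Smallest RMSD over random rotations (centroids aligned)."""
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_rotations):
        q = rng.normal(size=4)
        rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        best = min(best, float(np.sqrt(np.mean(np.sum((mc @ rot.T - tc) ** 2, axis=1)))))
    return best
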