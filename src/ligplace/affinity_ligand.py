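"""Ligand-based affinity prediction: atom-pair kernels + support-vector
regression, with binder classification at the 10 µM assay limit.

The working hypothesis is that similar ligands bind a common receptor with
similar affinity. Compounds are encoded as count fingerprints over typed
atom pairs — key = (type_i, type_j, topological distance), atom type =
(element, number of heavy neighbours, number of π electrons) — compared
with a min/max (Tanimoto) kernel, and regressed against pIC50 with ε-SVR
on the precomputed similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .chem_io import Molecule
from .errors import InputError

AtomPairKey = tuple[tuple, tuple, int]


@dataclass(frozen=True)
class AtomPairFingerprint:
    """Sparse counts over canonicalized (type, type, distance) keys."""

    counts: dict[AtomPairKey, int]

    def __len__(self) -> int:
        return len(self.counts)


def _atom_type(atom: Chem.Atom) -> tuple:
    n_heavy = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() != 1)
    if atom.GetIsAromatic():
        n_pi = 1
    else:
        n_pi = sum(
            int(round(b.GetBondTypeAsDouble() - 1.0))
            for b in atom.GetBonds()
            if b.GetBondTypeAsDouble() > 1.0
        )
    return (atom.GetSymbol(), n_heavy, n_pi)


def atom_pair_fp(mol: Molecule) -> AtomPairFingerprint:
    """Typed atom-pair count fingerprint over the heavy-atom graph.

    One count per unordered heavy-atom pair at its shortest-path bond
    distance (>= 1). A single heavy atom yields an empty fingerprint;
    a disconnected graph is rejected.
    """
    rd = Chem.RemoveHs(Chem.Mol(mol.rdkit_mol), sanitize=False)
    Chem.SanitizeMol(rd, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    if len(Chem.GetMolFrags(rd)) > 1:
        raise InputError(f"molecule {mol.name!r} is disconnected")
    n = rd.GetNumAtoms()
    types = [_atom_type(a) for a in rd.GetAtoms()]
    dmat = Chem.GetDistanceMatrix(rd)
    counts: dict[AtomPairKey, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dmat[i, j])
            ta, tb = sorted((types[i], types[j]))
            key = (ta, tb, d)
            counts[key] = counts.get(key, 0) + 1
    return AtomPairFingerprint(counts=counts)


def tanimoto_kernel(
    a: AtomPairFingerprint, b: AtomPairFingerprint, binary: bool = False
) -> float:
    """Min/max similarity Σ min / Σ max over the key union (Tanimoto on sets
    when `binary`)."""
    if not a.counts and not b.counts:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    num = den = 0.0
    for key in set(a.counts) | set(b.counts):
        ca = a.counts.get(key, 0)
        cb = b.counts.get(key, 0)
        if binary:
            ca, cb = int(ca > 0), int(cb > 0)
        num += min(ca, cb)
        den += max(ca, cb)
    return num / den if den else 0.0


def kernel_matrix(
    fps_a: list[AtomPairFingerprint],
    fps_b: list[AtomPairFingerprint] | None = None,
    binary: bool = False,
) -> np.ndarray:
    """Pairwise similarity matrix; symmetric with unit diagonal when square."""
    fps_b = fps_a if fps_b is None else fps_b
    out = np.empty((len(fps_a), len(fps_b)))
    for i, fa in enumerate(fps_a):
        for j, fb in enumerate(fps_b):
            out[i, j] = tanimoto_kernel(fa, fb, binary=binary)
    return out


@dataclass
class AffinityKernelModel:
    """Fitted ε-SVR on a precomputed similarity kernel."""

    train_fps: list[AtomPairFingerprint]
    labels: np.ndarray  # pIC50 / pKd
    svr: SVR
    C: float
    epsilon: float
    binary: bool = False
    extras: dict = field(default_factory=dict)

    def predict(self, fps: list[AtomPairFingerprint]) -> np.ndarray:
        if not fps:
            return np.empty(0)
        k = kernel_matrix(fps, self.train_fps, binary=self.binary)
        return self.svr.predict(k)


def fit_svr(
    K: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    train_fps: list[AtomPairFingerprint] | None = None,
    binary: bool = False,
) -> AffinityKernelModel:
    """Fit ε-SVR on a precomputed (symmetric) similarity matrix.

    A tiny ridge is added to the diagonal to absorb numerical asymmetry of
    the PSD kernel. Deterministic for fixed inputs.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InputError("kernel matrix must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise InputError("kernel matrix must be symmetric")
    if len(y) != K.shape[0]:
        raise InputError("label vector length does not match kernel size")
    Kr = K + 1e-10 * np.eye(len(K))
    svr = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=1e-5)
    svr.fit(Kr, y)
    return AffinityKernelModel(
        train_fps=list(train_fps or []), labels=y, svr=svr, C=C, epsilon=epsilon,
        binary=binary,
    )


def select_hyperparameters(
    K: np.ndarray,
    y: np.ndarray,
    Cs=(0.1, 1.0, 10.0, 100.0),
    epsilons=(0.01, 0.1, 0.5),
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (C, ε) by k-fold cross-validated mean squared error on the kernel."""
    y = np.asarray(y, dtype=float)
    kf = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
    best = (np.inf, Cs[0], epsilons[0])
    for C in Cs:
        for eps in epsilons:
            errs = []
            for tr, te in kf.split(y):
                svr = SVR(kernel="precomputed", C=C, epsilon=eps, tol=1e-5)
                svr.fit(K[np.ix_(tr, tr)], y[tr])
                pred = svr.predict(K[np.ix_(te, tr)])
                errs.append(float(np.mean((pred - y[te]) ** 2)))
            score = float(np.mean(errs))
            if score < best[0]:
                best = (score, C, eps)
    return best[1], best[2]


def pic50_from_ic50_molar(ic50_m: np.ndarray) -> np.ndarray:
    """pIC50 = −log10(IC50 in molar units)."""
    ic50_m = np.asarray(ic50_m, dtype=float)
    if np.any(ic50_m <= 0):
        raise InputError("IC50 values must be positive")
    return -np.log10(ic50_m)


def collapse_duplicates(smiles: list[str], y: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Collapse duplicate SMILES to the median label (canonicalized)."""
    canon = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in smiles]
    groups: dict[str, list[float]] = {}
    order: list[str] = []
    for c, val in zip(canon, np.asarray(y, dtype=float)):
        if c not in groups:
            order.append(c)
        groups.setdefault(c, []).append(val)
    return order, np.array([float(np.median(groups[c])) for c in order])


def predict_and_rank(
    model: AffinityKernelModel,
    fps: list[AtomPairFingerprint],
    ids: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Predict affinities and rank descending (tightest binder first).

    Ties break deterministically on compound id.
    """
    ids = ids or [f"cmpd{i}" for i in range(len(fps))]
    if len(ids) != len(fps):
        raise InputError("ids and fingerprints differ in length")
    preds = model.predict(fps)
    order = sorted(zip(ids, preds), key=lambda t: (-t[1], t[0]))
    return [(cid, float(p)) for cid, p in order]


def classify_binders(
    predictions: list[tuple[str, float]], threshold_molar: float = 10e-6
) -> dict[str, bool]:
    """Label compounds as binders when predicted affinity is strictly tighter
    than the assay limit (default 10 µM, i.e. pKd > 5.0 strictly)."""
    p_threshold = -np.log10(threshold_molar)
    return {cid: bool(p > p_threshold) for cid, p in predictions}
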