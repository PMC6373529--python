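"""Conformer generation, Gaussian shape/feature overlap, and rigid overlay.

Conformers are generated with distance-geometry embedding (ETKDG) followed
by force-field relaxation, deduplicated on heavy-atom RMSD. Conformers are
compared to a reference (the template's crystallographic ligand) with a
ROCS-style combined score:

    combo = shape_tanimoto + color_tanimoto  in [0, 2]

where both terms are first-order Gaussian-volume overlap Tanimotos — over
heavy atoms for shape, over class-matched pharmacophore feature points for
"color". The overlay search aligns principal axes (4 proper axis-flip
starts) and refines the 6 rigid degrees of freedom against the shape
overlap; color is evaluated at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from ._geometry import RigidTransform, kabsch, principal_axes, rotation_from_vector
from .chem_io import Molecule
from .errors import InputError, StageError

logger = logging.getLogger(__name__)

# --- Gaussian representation ------------------------------------------------
# Each atom is a spherical Gaussian rho(r) = p * exp(-alpha |r - c|^2) with
# p = 2.7 and alpha = KAPPA / radius^2. KAPPA is fixed so that the Gaussian
# self-overlap integral of an isolated atom equals its hard-sphere volume:
# p^2 (pi / 2 alpha)^{3/2} = 4/3 pi r^3.
PREFACTOR = 2.7
KAPPA = 0.5 * (3.0 * PREFACTOR**2 * np.sqrt(np.pi) / 4.0) ** (2.0 / 3.0)

# Bondi van der Waals radii (Å) for shape; feature pseudo-atoms use 1.0 Å.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "B": 1.92, "Si": 2.10,
}
DEFAULT_RADIUS = 1.70
FEATURE_RADIUS = 1.0

DEDUP_RMSD = 0.25  # Å, heavy-atom threshold below which conformers are duplicates

# Pharmacophore feature definitions (SMARTS), version 1.
FEATURE_SMARTS_VERSION = 1
FEATURE_SMARTS: dict[str, list[str]] = {
    "donor": ["[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),$([n;H1])]"],
    "acceptor": [
        "[$([O;H0;v2;!$(O=*)]),$([O;-;!$(*-N=O)]),$([o;H0;X2]),$(O=[C,S,P,N])]",
        "[$([N;v3;H0;!$(N=*);!+]),$([n;H0;X2])]",
    ],
    "anion": ["[-1,-2]", "[$([O;H1]C=O)]"],
    "cation": ["[+1,+2;!$([N+](=O)[O-])]", "[$([N;H2,H3;v3;!$(NC=O);!$(Na)])]"],
    "hydrophobe": [
        "[C;!$(C~[#7,#8,#15,#16]);!$(C#*)]",
        "[S;$(S(C)C)]",
        "[F,Cl,Br,I;$(*C)]",
    ],
    # aromatic ring centroids are handled geometrically, not via SMARTS
}
FEATURE_CLASSES = ("donor", "acceptor", "anion", "cation", "hydrophobe", "aromatic")


@dataclass
class ConformerEnsemble:
    """A molecule with m deduplicated conformers, ranked by strain energy."""

    molecule: Molecule
    energies: list[float]  # kcal/mol-scale force-field energies, one per conformer

    @property
    def n_conformers(self) -> int:
        return self.molecule.n_conformers


@dataclass(frozen=True)
class OverlayScore:
    shape_tanimoto: float
    color_tanimoto: float
    transform: RigidTransform

    @property
    def combo(self) -> float:
        return self.shape_tanimoto + self.color_tanimoto


# ---------------------------------------------------------------------------
# Conformer generation
# ---------------------------------------------------------------------------


def generate_conformers(
    mol: Molecule, max_confs: int = 500, seed: int = 0
) -> ConformerEnsemble:
    """Sample up to `max_confs` strain-relaxed conformers, deterministically.

    ETKDG distance-geometry embedding with the given seed, MMFF94 (UFF
    fallback) relaxation, then duplicate removal at a heavy-atom best-fit
    RMSD below 0.25 Å. Conformers come back sorted by relaxed energy.
    """
    if max_confs < 1:
        raise InputError("max_confs must be >= 1")
    work = Chem.Mol(mol.rdkit_mol)
    work.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    params.useRandomCoords = False
    ids = AllChem.EmbedMultipleConfs(work, numConfs=int(max_confs), params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(work, numConfs=int(max_confs), params=params)
    if len(ids) == 0:
        raise StageError("conformers", f"embedding failed for {mol.name!r}")

    energies = _relax_all(work)

    # energy-sorted, then greedy dedup on heavy-atom best RMSD
    order = sorted(range(len(energies)), key=lambda i: (energies[i], i))
    heavy = Chem.RemoveHs(Chem.Mol(work))
    kept: list[int] = []
    for i in order:
        dup = False
        for j in kept:
            if rdMolAlign.GetBestRMS(heavy, heavy, prbId=i, refId=j) < DEDUP_RMSD:
                dup = True
                break
        if not dup:
            kept.append(i)

    out = Chem.Mol(work)
    out.RemoveAllConformers()
    for new_id, i in enumerate(kept):
        conf = Chem.Conformer(work.GetConformer(i))
        conf.SetId(new_id)
        out.AddConformer(conf, assignId=False)
    result = Molecule(out, name=mol.name)
    return ConformerEnsemble(molecule=result, energies=[energies[i] for i in kept])


def _relax_all(work: Chem.Mol) -> list[float]:
    try:
        res = AllChem.MMFFOptimizeMoleculeConfs(work, maxIters=500, numThreads=1)
        if all(code == 0 or code == 1 for code, _ in res):
            return [float(e) for _, e in res]
    except Exception:
        pass
    res = AllChem.UFFOptimizeMoleculeConfs(work, maxIters=500, numThreads=1)
    return [float(e) for _, e in res]


# ---------------------------------------------------------------------------
# Gaussian volume overlap
# ---------------------------------------------------------------------------


def _alphas(elements: list[str]) -> np.ndarray:
    radii = np.array([VDW_RADII.get(el, DEFAULT_RADIUS) for el in elements])
    return KAPPA / radii**2


def gaussian_overlap_volume(
    xa: np.ndarray, alpha_a: np.ndarray, xb: np.ndarray, alpha_b: np.ndarray
) -> float:
    """First-order overlap volume of two sets of atomic Gaussians (Å³)."""
    if len(xa) == 0 or len(xb) == 0:
        return 0.0
    d2 = cdist(xa, xb, metric="sqeuclidean")
    s = alpha_a[:, None] + alpha_b[None, :]
    prod = alpha_a[:, None] * alpha_b[None, :]
    v = PREFACTOR**2 * (np.pi / s) ** 1.5 * np.exp(-prod / s * d2)
    return float(v.sum())


def _shape_arrays(mol: Molecule, conf_id: int) -> tuple[np.ndarray, np.ndarray]:
    heavy = mol.is_heavy
    if not heavy.any():
        raise InputError(f"molecule {mol.name!r} has no heavy atoms")
    coords = mol.coords(conf_id)[heavy]
    alphas = _alphas([el for el, h in zip(mol.elements, heavy) if h])
    return coords, alphas


def shape_tanimoto(
    a: Molecule, b: Molecule, conf_a: int = 0, conf_b: int = 0
) -> float:
    """Gaussian shape Tanimoto V_AB / (V_AA + V_BB - V_AB) over heavy atoms."""
    xa, aa = _shape_arrays(a, conf_a)
    xb, ab = _shape_arrays(b, conf_b)
    return _tanimoto_from_volumes(xa, aa, xb, ab)


def _tanimoto_from_volumes(xa, aa, xb, ab) -> float:
    vab = gaussian_overlap_volume(xa, aa, xb, ab)
    vaa = gaussian_overlap_volume(xa, aa, xa, aa)
    vbb = gaussian_overlap_volume(xb, ab, xb, ab)
    denom = vaa + vbb - vab
    return float(vab / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Color (pharmacophore feature) overlap
# ---------------------------------------------------------------------------


def feature_points(mol: Molecule, conf_id: int = 0) -> dict[str, np.ndarray]:
    """Per-class 3D feature points, pattern-matched on the chemical graph.

    Classes: donor, acceptor, anion, cation, hydrophobe, plus aromatic ring
    centroids located geometrically.
    """
    coords = mol.coords(conf_id)
    rd = mol.rdkit_mol
    out: dict[str, np.ndarray] = {}
    for cls, patterns in FEATURE_SMARTS.items():
        idx: set[int] = set()
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            for match in rd.GetSubstructMatches(patt):
                idx.update(match)
        if idx:
            out[cls] = coords[sorted(idx)]
    centroids = []
    for ring in rd.GetRingInfo().AtomRings():
        if all(rd.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroids.append(coords[list(ring)].mean(axis=0))
    if centroids:
        out["aromatic"] = np.array(centroids)
    return out


def color_tanimoto_features(
    feats_a: dict[str, np.ndarray], feats_b: dict[str, np.ndarray]
) -> float:
    """Gaussian-overlap Tanimoto over class-matched feature points.

    Only features of the same class overlap. Defined as 0 when neither side
    has any features.
    """
    alpha = KAPPA / FEATURE_RADIUS**2
    vab = vaa = vbb = 0.0
    for cls in set(feats_a) | set(feats_b):
        xa = np.asarray(feats_a.get(cls, np.empty((0, 3))), dtype=float)
        xb = np.asarray(feats_b.get(cls, np.empty((0, 3))), dtype=float)
        na, nb = len(xa), len(xb)
        if na:
            vaa += gaussian_overlap_volume(xa, np.full(na, alpha), xa, np.full(na, alpha))
        if nb:
            vbb += gaussian_overlap_volume(xb, np.full(nb, alpha), xb, np.full(nb, alpha))
        if na and nb:
            vab += gaussian_overlap_volume(xa, np.full(na, alpha), xb, np.full(nb, alpha))
    denom = vaa + vbb - vab
    return float(vab / denom) if denom > 0 else 0.0


def color_tanimoto(a: Molecule, b: Molecule, conf_a: int = 0, conf_b: int = 0) -> float:
    return color_tanimoto_features(feature_points(a, conf_a), feature_points(b, conf_b))


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

_AXIS_FLIPS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def overlay(
    moving: Molecule,
    reference: Molecule,
    conf_moving: int = 0,
    conf_ref: int = 0,
) -> OverlayScore:
    """Rigidly overlay `moving` onto `reference`, maximising shape overlap.

    Search: principal-axes alignment with the 4 proper axis-flip starts,
    then local refinement of the 6 rigid degrees of freedom on the shape
    overlap volume (Nelder–Mead). Color is scored at the optimum. For
    near-degenerate inertia tensors (linear molecules) the flip starts
    still cover the ambiguous axes.
    """
    xm, am = _shape_arrays(moving, conf_moving)
    xr, ar = _shape_arrays(reference, conf_ref)
    vaa = gaussian_overlap_volume(xm, am, xm, am)
    vbb = gaussian_overlap_volume(xr, ar, xr, ar)

    cm, _, axes_m = principal_axes(xm)
    cr, _, axes_r = principal_axes(xr)

    best: tuple[float, RigidTransform] | None = None
    for flip in _AXIS_FLIPS:
        r0 = axes_r @ flip @ axes_m.T
        t0 = cr - r0 @ cm
        start = RigidTransform(r0, t0)
        refined = _refine_shape(xm, am, xr, ar, start, cm)
        vab = gaussian_overlap_volume(refined.apply(xm), am, xr, ar)
        score = vab / (vaa + vbb - vab)
        if best is None or score > best[0]:
            best = (score, refined)

    shape = best[0]
    transform = best[1]

    feats_m = feature_points(moving, conf_moving)
    feats_m = {cls: transform.apply(pts) for cls, pts in feats_m.items()}
    color = color_tanimoto_features(feats_m, feature_points(reference, conf_ref))
    return OverlayScore(shape_tanimoto=float(shape), color_tanimoto=float(color), transform=transform)


def _refine_shape(xm, am, xr, ar, start: RigidTransform, pivot: np.ndarray) -> RigidTransform:
    """Local 6-DOF refinement of the shape overlap from a rigid start."""
    x0 = start.apply(xm)
    c0 = start.apply(pivot[None, :])[0]

    def objective(p):
        rot = rotation_from_vector(p[:3])
        pts = (x0 - c0) @ rot.T + c0 + p[3:]
        return -gaussian_overlap_volume(pts, am, xr, ar)

    res = minimize(
        objective,
        np.zeros(6),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 1200},
    )
    p = res.x if res.fun <= objective(np.zeros(6)) else np.zeros(6)
    rot = rotation_from_vector(p[:3])
    local = RigidTransform(rot, c0 + p[3:] - rot @ c0)
    return local.compose(start)


def select_top_conformers(
    ens: ConformerEnsemble, ref: Molecule, k: int = 10, conf_ref: int = 0
) -> list[tuple[Molecule, OverlayScore]]:
    """Overlay every ensemble conformer onto `ref`, keep the best k by combo.

    Each returned conformer is a single-conformer Molecule already moved into
    the reference (binding-site) frame. The ordering is independent of the
    input conformer order: ties on combo break on the overlaid coordinates.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    scored: list[tuple[Molecule, OverlayScore, bytes]] = []
    for conf_id in range(ens.n_conformers):
        ov = overlay(ens.molecule, ref, conf_moving=conf_id, conf_ref=conf_ref)
        posed = _single_conformer(ens.molecule, conf_id)
        posed.set_coords(ov.transform.apply(posed.coords()))
        key = np.round(posed.coords(), 4).tobytes()
        scored.append((posed, ov, key))
    scored.sort(key=lambda t: (-t[1].combo, t[2]))
    return [(mol, ov) for mol, ov, _ in scored[:k]]


def _single_conformer(mol: Molecule, conf_id: int) -> Molecule:
    out = Chem.Mol(mol.rdkit_mol)
    out.RemoveAllConformers()
    conf = Chem.Conformer(mol.rdkit_mol.GetConformer(conf_id))
    conf.SetId(0)
    out.AddConformer(conf, assignId=False)
    m = Molecule(out, name=mol.name)
    if mol.partial_charges is not None:
        m.partial_charges = mol.partial_charges.copy()
    return m


# ---------------------------------------------------------------------------
# Self-docking site transfer
# ---------------------------------------------------------------------------


def superpose_template_to_site(template_complex, site_protein) -> RigidTransform:
    """Backbone (CA) superposition of a template onto a target site structure.

    Matches CA atoms by (chain, residue number) and returns the rigid
    transform carrying the template frame (including its bound ligand) onto
    the site structure — the self-docking "site-from" variant.
    """
    tp = template_complex.protein
    idx_t = {
        (tp.chains[i], int(tp.resseqs[i])): i
        for i in range(tp.n_atoms)
        if tp.names[i] == "CA"
    }
    idx_s = {
        (site_protein.chains[i], int(site_protein.resseqs[i])): i
        for i in range(site_protein.n_atoms)
        if site_protein.names[i] == "CA"
    }
    common = sorted(set(idx_t) & set(idx_s))
    if len(common) < 3:
        raise InputError("fewer than 3 matched CA atoms between template and site")
    mobile = tp.coords[[idx_t[k] for k in common]]
    target = site_protein.coords[[idx_s[k] for k in common]]
    return kabsch(mobile, target)
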