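"""Synthetic test-input generators: toy pockets, template ladders, affinity sets.

Every generator is a pure function of its spec (including the seed), so
fixtures regenerate byte-identically and no external structures or
databases are needed to exercise the full pipeline.

The pocket generator plants a known ligand pose and moulds a shell of
glycine-like pseudo-residues around it at a fixed clearance, so the planted
orientation is the unique snug pose. The affinity generator emulates a
censored bioassay table: a "binder" family decorated from a probe scaffold
(affinity a monotone function of atom-pair similarity to the probe) and a
chemically disjoint "non-binder" family whose similarity to the probe is
exactly zero, mirroring compound sets dominated by measurements pinned at
the 10 µM assay limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from ._geometry import fibonacci_sphere, principal_axes
from .affinity_ligand import atom_pair_fp, tanimoto_kernel
from .chem_io import ComplexStructure, Molecule, ProteinStructure, assign_partial_charges, read_smiles
from .conformers import generate_conformers
from .errors import InputError
from .template_select import TemplateRecord

# glycine-like pseudo-residue: local atom offsets (Å) and rough charges
_RESIDUE_ATOMS = (
    ("N", "N", np.array([0.0, 0.0, 0.0]), -0.35),
    ("C", "CA", np.array([1.2, 0.6, 0.0]), 0.10),
    ("C", "C", np.array([2.2, -0.3, 0.6]), 0.45),
    ("O", "O", np.array([2.2, -1.5, 0.4]), -0.20),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    # pocket
    ligand_smiles: str = "c1ccc2ccccc2c1"  # naphthalene: rigid, elongated
    n_shell: int = 80
    margin: float = 3.9  # Å nearest-atom contact distance of shell residues
    cavity_radius: float | None = None  # spherical cavity override (Å)
    equilibrate: bool = True  # record the planted truth at its energy minimum
    # template ladder
    ladder_k: int = 3
    # affinity set
    affinity_slope: float = 4.0  # pIC50 = 9 − slope·(1 − sim to probe)
    affinity_probe: str = "Cc1ccc(C)cc1"
    nonbinder_pic50: float = 4.5  # true affinity of the censored family
    binder_fraction: float = 1.0
    noise_sigma: float = 0.0


# ---------------------------------------------------------------------------
# Pocket
# ---------------------------------------------------------------------------


def make_pocket_complex(spec: FixtureSpec) -> tuple[ComplexStructure, np.ndarray]:
    """A planted ligand inside a moulded pseudo-protein shell.

    The ligand is embedded (seeded), centred and axis-aligned; shell
    residues sit at ligand-surface + margin along quasi-uniform directions
    (or on a sphere of `cavity_radius` when given). Returns the complex and
    the planted truth coordinates (all atoms).
    """
    lig = _planted_ligand(spec)
    coords = lig.coords()
    bound = float(np.linalg.norm(coords, axis=1).max())

    dirs = fibonacci_sphere(spec.n_shell)
    if spec.cavity_radius is not None:
        if spec.cavity_radius < bound + 1.5:
            raise InputError(
                f"ligand (radius {bound:.1f} Å) larger than cavity "
                f"({spec.cavity_radius:.1f} Å)"
            )
        radii = np.full(spec.n_shell, float(spec.cavity_radius))
    else:
        if spec.margin < 1.5:
            raise InputError(f"margin {spec.margin} Å leaves no room for the ligand")
        # mould the shell to the ligand: spherical dilation of the atom cloud,
        # so every shell point sits exactly `margin` from its nearest atom
        radii = _dilation_radii(coords, dirs, spec.margin)

    rows = []
    for k, (u, r) in enumerate(zip(dirs, radii)):
        # local frame at the shell point, deterministic
        z = u
        helper = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        x = np.cross(z, helper)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        frame = np.column_stack([x, y, z])
        for el, name, offset, q in _RESIDUE_ATOMS:
            pos = u * r + frame @ (offset * 0.5)
            rows.append((el, name, "GLY", k + 1, "A", pos, q))

    protein = ProteinStructure(
        elements=[r[0] for r in rows],
        names=[r[1] for r in rows],
        resnames=[r[2] for r in rows],
        resseqs=np.array([r[3] for r in rows]),
        chains=[r[4] for r in rows],
        coords=np.array([r[5] for r in rows]),
        is_water=np.zeros(len(rows), dtype=bool),
        is_hetero=np.zeros(len(rows), dtype=bool),
        charges=np.array([r[6] for r in rows]),
    )
    complex_ = ComplexStructure(
        protein=protein,
        ligand=lig,
        provenance={"fixture": "pocket", "seed": spec.seed},
    )
    if spec.cavity_radius is None and spec.equilibrate:
        # record the planted truth at mechanical equilibrium of the pocket's
        # own energy model, as a crystallographic pose would be; a few seeded
        # jittered restarts make sure the recorded pose is the basin bottom
        from .energetics import score_complex
        from .pose_pipeline import _jitter, _rotatable_bonds, relax_pose

        best, _ = relax_pose(complex_, seed=spec.seed)
        best_score = score_complex(best).score
        rng = np.random.default_rng(spec.seed)
        torsions = _rotatable_bonds(complex_.ligand)
        for _ in range(10):
            trial_lig = complex_.ligand.copy()
            trial_lig.set_coords(_jitter(complex_.ligand_coords(), torsions, rng))
            trial = ComplexStructure(protein=protein, ligand=trial_lig)
            relaxed, _ = relax_pose(trial, seed=spec.seed)
            s = score_complex(relaxed).score
            if s < best_score - 1e-6:
                best, best_score = relaxed, s
        complex_ = best
        complex_.provenance.update(fixture="pocket", seed=spec.seed)
    return complex_, complex_.ligand_coords().copy()


def _dilation_radii(coords: np.ndarray, dirs: np.ndarray, margin: float) -> np.ndarray:
    """Ray-cast radii of the ligand surface dilated by `margin`.

    For direction u, the largest r with |r·u − x_i| = margin over atoms whose
    perpendicular distance to the ray is below margin; falls back to the
    support function for rays that graze no atom.
    """
    proj = coords @ dirs.T  # (atoms, dirs) projections onto each direction
    perp2 = (coords**2).sum(axis=1)[:, None] - proj**2
    inside = perp2 <= margin**2
    root = np.sqrt(np.where(inside, margin**2 - perp2, 0.0))
    candidate = np.where(inside, proj + root, -np.inf)
    radii = candidate.max(axis=0)
    fallback = proj.max(axis=0) + margin
    return np.where(np.isfinite(radii), radii, fallback)


def _planted_ligand(spec: FixtureSpec) -> Molecule:
    mol = read_smiles(spec.ligand_smiles, name="planted")
    ens = generate_conformers(mol, max_confs=1, seed=spec.seed)
    lig = ens.molecule
    xyz = lig.coords()
    c, _, axes = principal_axes(xyz)
    lig.set_coords((xyz - c) @ axes)  # centred, principal axes on x/y/z
    return assign_partial_charges(lig)


# ---------------------------------------------------------------------------
# Template ladder
# ---------------------------------------------------------------------------


def make_template_ladder(
    target_smiles: str, k: int | None = None, spec: FixtureSpec | None = None
) -> list[TemplateRecord]:
    """Templates whose ligands are progressive heavy-atom deletions of the
    target, giving a known, decreasing similarity ladder.

    Rung i deletes i terminal heavy atoms, so with n target heavy atoms the
    expected MCS size is n − i and the similarity (n − i)/n. Each rung gets
    its own moulded pocket complex.
    """
    spec = spec or FixtureSpec()
    k = spec.ladder_k if k is None else k
    if k < 0:
        raise InputError("ladder size must be >= 0")
    records = []
    smiles = target_smiles
    for i in range(k):
        if i > 0:
            smiles = _delete_terminal_heavy(smiles)
            if smiles is None:
                break
        rung_spec = FixtureSpec(
            seed=spec.seed + i,
            ligand_smiles=smiles,
            n_shell=spec.n_shell,
            margin=spec.margin,
            equilibrate=False,  # ladder pockets only anchor the 3D frame
        )
        complex_, _ = make_pocket_complex(rung_spec)
        records.append(
            TemplateRecord(
                id=f"T{i:02d}",
                complex=complex_,
                ligand_2d=read_smiles(smiles, name=f"T{i:02d}-lig"),
            )
        )
    return records


def _delete_terminal_heavy(smiles: str) -> str | None:
    """Remove one terminal heavy atom (lowest index), keeping a valid graph."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() <= 2:
        return None
    for atom in mol.GetAtoms():
        if atom.GetDegree() == 1 and not atom.GetIsAromatic():
            rw = Chem.RWMol(mol)
            rw.RemoveAtom(atom.GetIdx())
            out = rw.GetMol()
            try:
                Chem.SanitizeMol(out)
            except Exception:
                continue
            return Chem.MolToSmiles(out)
    # fully aromatic target: append-then-delete is not possible; shrink ring systems
    return None


# ---------------------------------------------------------------------------
# Affinity tables
# ---------------------------------------------------------------------------

_BINDER_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C"]
_NONBINDER_BACKBONES = [
    "OO", "NN", "NO", "NNO", "OP(=O)(O)O", "NP(=O)(O)O", "OP(=O)(O)OP(=O)(O)O",
    "NP(=O)(N)O", "OS(=O)(=O)O", "NS(=O)(=O)N", "NS(=O)(=O)O", "OO[Si](O)(O)OO",
]


def _binder_grammar(n: int, rng: np.random.Generator) -> list[str]:
    """Alkyl-decorated benzenes: scaffold-decoration grammar sharing atom-pair
    keys with the probe, giving a continuous similarity spread."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        n_sub = int(rng.integers(0, 5))
        subs = [str(rng.choice(_BINDER_SUBSTITUENTS)) for _ in range(n_sub)]
        core = "c1ccccc1" if not subs else _decorated_benzene(subs)
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(core))
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


def _decorated_benzene(subs: list[str]) -> str:
    positions = ["c1", "c", "c", "c", "c", "c"]
    smiles = ""
    for i in range(6):
        smiles += positions[i]
        if i < len(subs):
            smiles += f"({subs[i]})"
    return smiles + "1"


def _nonbinder_grammar(n: int, rng: np.random.Generator) -> list[str]:
    pool = list(_NONBINDER_BACKBONES)
    out = []
    for i in range(n):
        out.append(pool[int(rng.integers(0, len(pool)))] if i >= len(pool) else pool[i])
    return out


def make_affinity_set(
    n_train: int = 60,
    n_test: int = 30,
    spec: FixtureSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic (SMILES, pIC50) train/test tables from a known rule.

    Binder-family labels follow pIC50 = 9 − slope·(1 − sim(probe)) + noise;
    the non-binder family (similarity exactly 0 to the probe family) is
    labelled at `nonbinder_pic50`, below the 10 µM detection limit.
    Columns: id, smiles, pic50, ic50_nM, is_binder (truth).
    """
    spec = spec or FixtureSpec()
    if spec.noise_sigma < 0:
        raise InputError("noise sigma must be >= 0")
    rng = np.random.default_rng(spec.seed)
    probe_fp = atom_pair_fp(read_smiles(spec.affinity_probe))

    def build(n: int, tag: str) -> pd.DataFrame:
        n_bind = int(round(n * spec.binder_fraction))
        binders = _binder_grammar(n_bind, rng)
        nonbinders = _nonbinder_grammar(n - n_bind, rng)
        rows = []
        for i, smi in enumerate(binders + nonbinders):
            is_binder = i < n_bind
            if is_binder:
                sim = tanimoto_kernel(atom_pair_fp(read_smiles(smi)), probe_fp)
                pic50 = 9.0 - spec.affinity_slope * (1.0 - sim)
            else:
                pic50 = spec.nonbinder_pic50
            pic50 += rng.normal(scale=spec.noise_sigma) if spec.noise_sigma > 0 else 0.0
            rows.append(
                {
                    "id": f"{tag}{i:03d}",
                    "smiles": smi,
                    "pic50": pic50,
                    "ic50_nM": 10 ** (9 - pic50),
                    "is_binder": is_binder,
                }
            )
        return pd.DataFrame(rows)

    return build(n_train, "train"), build(n_test, "test")
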