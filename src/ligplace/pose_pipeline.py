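"""End-to-end pose prediction: template → conformers → relax → score → rank.

The refinement stage is a deterministic local relaxation (rigid-body plus
ligand-torsion coordinate descent on E_vdw + 0.1·E_elec) applied to each
overlaid conformer from several seeded-jitter restarts; poses are then
ranked by the full weighted pose score (lower is better) and the top five
form the submission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

from ._geometry import rotation_from_vector
from .chem_io import ComplexStructure, Molecule, assign_partial_charges
from .config import RunConfig
from .conformers import generate_conformers, select_top_conformers
from .energetics import EnergyReport, NonbondedParams, coulomb_energy, lj_energy, score_complex
from .errors import InputError, StageError
from .template_select import TemplateRecord, select_template

logger = logging.getLogger(__name__)

ROTATABLE_SMARTS = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")

RELAX_MAX_ITERS = 200
RELAX_TOL = 1e-3


@dataclass
class PoseSet:
    """Ranked poses for one target; the top-`submission_size` are the submission."""

    target_id: str
    poses: list[tuple[ComplexStructure, EnergyReport]]
    provenance: dict = field(default_factory=dict)
    submission_size: int = 5

    def __post_init__(self):
        if not self.poses:
            raise InputError(f"pose set for {self.target_id!r} is empty")
        scores = [r.score for _, r in self.poses]
        if scores != sorted(scores):
            raise InputError("poses must be sorted by ascending score")

    @property
    def submission(self) -> list[tuple[ComplexStructure, EnergyReport]]:
        return self.poses[: self.submission_size]


# ---------------------------------------------------------------------------
# Interface
# ---------------------------------------------------------------------------


def interface_residues(
    complex_: ComplexStructure, cutoff: float = 5.0
) -> set[tuple[str, int]]:
    """Protein residues with any atom within `cutoff` Å of any ligand atom."""
    prot = complex_.protein
    d = cdist(prot.coords, complex_.ligand_coords()).min(axis=1)
    out: set[tuple[str, int]] = set()
    for i in np.where(d <= cutoff)[0]:
        out.add((prot.chains[i], int(prot.resseqs[i])))
    return out


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------


def _rotatable_bonds(mol: Molecule) -> list[tuple[int, int, np.ndarray]]:
    """(i, j, mask-of-atoms-that-move-when-rotating-about-i→j)."""
    rd = mol.rdkit_mol
    out = []
    for i, j in rd.GetSubstructMatches(ROTATABLE_SMARTS):
        bond = rd.GetBondBetweenAtoms(i, j)
        em = Chem.RWMol(rd)
        em.RemoveBond(i, j)
        frags = Chem.GetMolFrags(em.GetMol(), asMols=False, sanitizeFrags=False)
        side_j = next(f for f in frags if j in f)
        if i in side_j:  # ring bond slipped through; skip
            continue
        mask = np.zeros(mol.n_atoms, dtype=bool)
        mask[list(side_j)] = True
        if mask.sum() <= mol.n_atoms - mask.sum():
            out.append((i, j, mask))
        else:
            mask_i = ~mask
            out.append((j, i, mask_i))
    return out


def _rotate_about_axis(coords, anchor, axis, angle, mask):
    axis = axis / np.linalg.norm(axis)
    rot = rotation_from_vector(axis * angle)
    out = coords.copy()
    out[mask] = (coords[mask] - anchor) @ rot.T + anchor
    return out


class _RelaxObjective:
    """E_vdw + 0.1·E_elec of the complex as a function of ligand coordinates."""

    def __init__(self, complex_: ComplexStructure, params: NonbondedParams):
        self.complex = complex_
        self.params = params
        self.template = complex_.ligand.copy()
        self.has_charges = (
            complex_.protein.charges is not None
            and complex_.ligand.partial_charges is not None
        )

    def __call__(self, coords: np.ndarray) -> float:
        self.template.set_coords(coords)
        trial = ComplexStructure(
            protein=self.complex.protein, ligand=self.template,
            provenance=self.complex.provenance,
        )
        try:
            e = lj_energy(trial, self.params)
            if self.has_charges:
                e += 0.1 * coulomb_energy(trial, self.params)
        except InputError:  # sub-0.1 Å clash: treat as an impossible geometry
            return float("inf")
        return e


def relax_pose(
    complex_: ComplexStructure,
    params: NonbondedParams | None = None,
    seed: int = 0,
    max_iters: int = RELAX_MAX_ITERS,
    tol: float = RELAX_TOL,
) -> tuple[ComplexStructure, float]:
    """Deterministic local relaxation of the ligand pose (protein rigid).

    Coordinate descent over rigid-body translation/rotation and ligand
    torsions on E_vdw + 0.1·E_elec; only strictly improving moves are
    accepted, so the final energy never exceeds the initial one. A pose
    starting in a hard clash (non-finite energy) is jittered with a seeded
    random displacement and retried. Returns (relaxed complex, energy).
    """
    params = params or NonbondedParams()
    objective = _RelaxObjective(complex_, params)
    coords = complex_.ligand_coords().copy()
    energy = objective(coords)

    if not np.isfinite(energy):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            trial = coords + rng.normal(scale=0.3, size=coords.shape)
            e = objective(trial)
            if np.isfinite(e):
                logger.warning("clashing start pose jittered before relaxation")
                coords, energy = trial, e
                break
        else:
            raise StageError("relax", "pose stuck in a hard clash after 20 jitters")

    torsions = _rotatable_bonds(complex_.ligand)
    iters = 0
    while iters < max_iters:
        start_energy = energy
        centroid = coords.mean(axis=0)
        # rigid translation, one axis at a time
        for ax in range(3):
            def f_trans(s, ax=ax):
                trial = coords.copy()
                trial[:, ax] += s
                return objective(trial)
            coords, energy = _line_search(f_trans, coords, energy,
                                          lambda s, ax=ax: _shift(coords, ax, s), 1.0)
            iters += 1
        # rigid rotation about the centroid, one axis at a time
        for ax in range(3):
            unit = np.eye(3)[ax]
            def apply_rot(s, unit=unit, centroid=centroid):
                rot = rotation_from_vector(unit * s)
                return (coords - centroid) @ rot.T + centroid
            coords, energy = _line_search(
                lambda s, a=apply_rot: objective(a(s)), coords, energy, apply_rot, 0.6
            )
            iters += 1
        # ligand torsions
        for i, j, mask in torsions:
            def apply_tor(s, i=i, j=j, mask=mask):
                return _rotate_about_axis(coords, coords[j], coords[j] - coords[i], s, mask)
            coords, energy = _line_search(
                lambda s, a=apply_tor: objective(a(s)), coords, energy, apply_tor, np.pi
            )
            iters += 1
        if start_energy - energy < tol:
            break

    relaxed_lig = complex_.ligand.copy()
    relaxed_lig.set_coords(coords)
    relaxed = ComplexStructure(
        protein=complex_.protein,
        ligand=relaxed_lig,
        provenance={**complex_.provenance, "relaxed": True},
    )
    return relaxed, float(energy)


def _shift(coords, ax, s):
    out = coords.copy()
    out[:, ax] += s
    return out


def _line_search(f, coords, energy, apply, half_width):
    res = minimize_scalar(
        f, bounds=(-half_width, half_width), method="bounded",
        options={"xatol": 1e-4, "maxiter": 40},
    )
    if np.isfinite(res.fun) and res.fun < energy - 1e-12:
        return apply(res.x), float(res.fun)
    return coords, energy


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    target_smiles_mol: Molecule | str,
    library: list[TemplateRecord],
    config: RunConfig | None = None,
) -> PoseSet:
    """Template-guided pose prediction for one target compound.

    Stages: template selection, conformer generation, shape/feature overlay
    into the template site, seeded-jitter restarts through local relaxation,
    full pose scoring, ranking. Deterministic for a fixed config seed.
    """
    config = config or RunConfig()
    if not library:
        raise StageError("template", "template library is empty")

    from .chem_io import read_smiles  # local import to keep module load light

    target = (
        read_smiles(target_smiles_mol)
        if isinstance(target_smiles_mol, str)
        else target_smiles_mol
    )

    record, sim = select_template(target, library)
    template_ligand = record.complex.ligand

    try:
        ensemble = generate_conformers(target, max_confs=config.max_confs, seed=config.seed)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("conformers", str(exc))
    if ensemble.n_conformers == 0:
        raise StageError("conformers", f"no conformers for {target.name!r}")

    selected = select_top_conformers(
        ensemble, template_ligand, k=config.top_confs, conf_ref=record.complex.conf_id
    )

    params = NonbondedParams(cutoff=config.nonbonded_cutoff)
    rng = np.random.default_rng(config.seed)
    poses: list[tuple[ComplexStructure, EnergyReport]] = []
    for conf_idx, (posed, overlay_score) in enumerate(selected):
        posed = assign_partial_charges(posed)
        torsions = _rotatable_bonds(posed)
        for restart in range(config.n_restarts):
            lig = posed.copy()
            if restart > 0:
                lig.set_coords(_jitter(lig.coords(), torsions, rng))
            start = ComplexStructure(
                protein=record.complex.protein,
                ligand=lig,
                provenance={
                    "template_id": record.id,
                    "template_similarity": sim.similarity,
                    "conformer": conf_idx,
                    "restart": restart,
                    "seed": config.seed,
                    "combo": overlay_score.combo,
                    "refinement": "local-relaxation",
                },
            )
            try:
                relaxed, _ = relax_pose(start, params=params, seed=config.seed + restart)
            except StageError:
                continue
            report = score_complex(relaxed, params=params, weights=config.score_weights)
            poses.append((relaxed, report))

    if not poses:
        raise StageError("relax", "no pose survived refinement")
    poses.sort(key=lambda p: (p[1].score, p[0].provenance.get("conformer", 0),
                              p[0].provenance.get("restart", 0)))
    return PoseSet(
        target_id=target.name,
        poses=poses,
        provenance={
            "template_id": record.id,
            "template_similarity": sim.similarity,
            "seed": config.seed,
            "refinement": "local-relaxation",
        },
        submission_size=config.submission_size,
    )


def _jitter(coords, torsions, rng):
    """Seeded restart perturbation: small rigid wobble + torsion kicks."""
    centroid = coords.mean(axis=0)
    rot = rotation_from_vector(rng.normal(scale=0.08, size=3))
    out = (coords - centroid) @ rot.T + centroid + rng.normal(scale=0.3, size=3)
    for i, j, mask in torsions:
        out = _rotate_about_axis(
            out, out[j], out[j] - out[i], rng.uniform(-np.pi / 3, np.pi / 3), mask
        )
    return out
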