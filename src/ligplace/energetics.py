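"""Intermolecular energy terms and the re-weighted pose score.

The pose score is the weighted sum

    score = 1.0 * E_vdw + 0.1 * E_elec + 1.0 * E_desolv + 0.1 * E_AIR

with the electrostatic weight halved relative to the common 0.2 default —
the weighting used to rank refined poses. E_vdw and E_elec are OPLS-style
pairwise nonbonded energies with an 8.5 Å hard cutoff; E_desolv is an
empirical buried-surface-area desolvation potential (its units are
internal to the toolkit); E_AIR is an externally supplied restraint energy
that defaults to 0 because no restraints drive this protocol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._geometry import canonical_frame, fibonacci_sphere
from .chem_io import ComplexStructure
from .conformers import VDW_RADII, DEFAULT_RADIUS
from .errors import InputError

logger = logging.getLogger(__name__)

# OPLS-like per-element Lennard-Jones parameters (sigma Å, epsilon kcal/mol).
# Element-level coarse-graining of the united/all-atom tables; unknown
# elements fall back to a generic carbon-like default with a warning.
LJ_TABLE: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.030),
    "C": (3.55, 0.070),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.60, 0.355),
    "P": (3.74, 0.200),
    "F": (2.94, 0.061),
    "Cl": (3.40, 0.300),
    "Br": (3.47, 0.470),
    "I": (3.55, 0.600),
}
LJ_DEFAULT = (3.50, 0.100)

# Atomic solvation parameters (empirical units per Å² of surface area).
# Convention: E_desolv = sum_i sigma_solv(i) * (SASA_complex - SASA_free),
# so burying hydrophobic surface (sigma > 0) is favourable (negative).
SOLVATION_TABLE: dict[str, float] = {
    "C": 0.0126,
    "S": 0.0100,
    "N": -0.0070,
    "O": -0.0080,
    "H": 0.0,
    "F": 0.0090,
    "Cl": 0.0090,
    "Br": 0.0090,
    "I": 0.0090,
    "P": -0.0070,
}

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

MIN_PAIR_DISTANCE = 0.1  # Å; closer pairs are outside the model's validity
SASA_PROBE_RADIUS = 1.4  # Å
SASA_N_POINTS = 960  # deterministic sphere points per atom

DEFAULT_WEIGHTS = (1.0, 0.1, 1.0, 0.1)  # (vdw, elec, desolv, air)


@dataclass(frozen=True)
class NonbondedParams:
    """Nonbonded parameter set: LJ table, Coulomb constant, cutoff."""

    lj: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(LJ_TABLE))
    coulomb_constant: float = COULOMB_CONSTANT
    cutoff: float = 8.5

    def sigma_eps(self, element: str) -> tuple[float, float]:
        if element not in self.lj:
            logger.warning("no LJ parameters for %r; using element default", element)
            return LJ_DEFAULT
        return self.lj[element]


@dataclass(frozen=True)
class EnergyReport:
    e_vdw: float
    e_elec: float
    e_desolv: float
    e_air: float
    score: float


# ---------------------------------------------------------------------------
# Pairwise terms
# ---------------------------------------------------------------------------


def _complex_arrays(complex_: ComplexStructure):
    prot = complex_.protein
    lig = complex_.ligand
    return (
        prot.coords,
        list(prot.elements),
        prot.charges,
        complex_.ligand_coords(),
        lig.elements,
        lig.partial_charges,
    )


def _pair_distances(xp: np.ndarray, xl: np.ndarray) -> np.ndarray:
    d = cdist(xp, xl)
    if d.size and d.min() < MIN_PAIR_DISTANCE:
        raise InputError(
            f"intermolecular distance {d.min():.3f} Å below {MIN_PAIR_DISTANCE} Å: "
            "clash beyond model validity"
        )
    return d


def lj_energy(complex_: ComplexStructure, params: NonbondedParams | None = None) -> float:
    """Intermolecular Lennard-Jones energy (kcal/mol).

    Sum over protein–ligand pairs within the cutoff of
    4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6] with Lorentz–Berthelot mixing.
    """
    params = params or NonbondedParams()
    xp, ep, _, xl, el, _ = _complex_arrays(complex_)
    d = _pair_distances(xp, xl)
    sig_p, eps_p = _lj_arrays(ep, params)
    sig_l, eps_l = _lj_arrays(el, params)
    sig = 0.5 * (sig_p[:, None] + sig_l[None, :])
    eps = np.sqrt(eps_p[:, None] * eps_l[None, :])
    mask = d <= params.cutoff
    with np.errstate(divide="ignore"):
        sr6 = np.where(mask, (sig / np.maximum(d, 1e-12)) ** 6, 0.0)
    return float(np.sum(4.0 * eps * (sr6**2 - sr6) * mask))


def _lj_arrays(elements, params):
    pairs = [params.sigma_eps(el) for el in elements]
    return np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])


def coulomb_energy(
    complex_: ComplexStructure, params: NonbondedParams | None = None
) -> float:
    """Intermolecular Coulomb energy (kcal/mol), hard cutoff, unit dielectric."""
    params = params or NonbondedParams()
    xp, _, qp, xl, _, ql = _complex_arrays(complex_)
    if qp is None:
        raise InputError("protein partial charges missing")
    if ql is None:
        raise InputError("ligand partial charges missing")
    d = _pair_distances(xp, xl)
    mask = d <= params.cutoff
    qq = np.asarray(qp)[:, None] * np.asarray(ql)[None, :]
    with np.errstate(divide="ignore"):
        e = np.where(mask, qq / np.maximum(d, 1e-12), 0.0)
    return float(params.coulomb_constant * e.sum())


# ---------------------------------------------------------------------------
# Desolvation
# ---------------------------------------------------------------------------


def sasa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = SASA_PROBE_RADIUS,
    n_points: int = SASA_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley style.

    Deterministic Fibonacci-lattice sampling with `n_points` points per atom
    and a rolling probe of 1.4 Å.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    radii = np.array([VDW_RADII.get(el, DEFAULT_RADIUS) for el in elements]) + probe
    sphere = fibonacci_sphere(n_points)
    out = np.zeros(n)
    if n == 0:
        return out
    d = cdist(coords, coords)
    for i in range(n):
        neighbors = np.where((d[i] < radii[i] + radii) & (np.arange(n) != i))[0]
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
            if not accessible.any():
                break
        out[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return out


def desolvation_energy(complex_: ComplexStructure) -> float:
    """Empirical desolvation energy from buried solvent-accessible area.

    E_desolv = sum over all atoms of sigma_solv * (SASA_complex - SASA_free);
    partners far apart bury nothing and score ~0. Units are internal
    empirical units, consistent within the toolkit only.
    """
    xp, ep, _, xl, el, _ = _complex_arrays(complex_)
    all_coords = np.vstack([xp, xl])
    all_elements = list(ep) + list(el)
    # evaluate the numerical surface in the complex's canonical frame so the
    # term is invariant under global rigid motion of the complex
    center, axes = canonical_frame(all_coords)
    all_coords = (all_coords - center) @ axes
    xp_c, xl_c = all_coords[: len(xp)], all_coords[len(xp):]
    sasa_complex = sasa(all_coords, all_elements)
    sasa_free = np.concatenate([sasa(xp_c, ep), sasa(xl_c, el)])
    sigmas = np.array([SOLVATION_TABLE.get(e, 0.0) for e in all_elements])
    return float(np.sum(sigmas * (sasa_complex - sasa_free)))


# ---------------------------------------------------------------------------
# Pose score
# ---------------------------------------------------------------------------


def pose_score(
    e_vdw: float,
    e_elec: float,
    e_desolv: float,
    e_air: float = 0.0,
    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS,
) -> EnergyReport:
    """Weighted pose score over the four energy terms (lower is better)."""
    terms = (e_vdw, e_elec, e_desolv, e_air)
    if any(not math.isfinite(t) for t in terms):
        raise InputError(f"non-finite energy term in {terms}")
    score = sum(w * t for w, t in zip(weights, terms))
    return EnergyReport(
        e_vdw=float(e_vdw),
        e_elec=float(e_elec),
        e_desolv=float(e_desolv),
        e_air=float(e_air),
        score=float(score),
    )


def score_complex(
    complex_: ComplexStructure,
    params: NonbondedParams | None = None,
    e_air: float = 0.0,
    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS,
    include_desolv: bool = True,
) -> EnergyReport:
    """Compute all terms for a complex and combine them into the pose score.

    Electrostatics silently contributes 0 when either partner has no
    charges assigned (the term is then absent rather than an error, which
    matches scoring pipelines run on charge-free synthetic systems).
    """
    params = params or NonbondedParams()
    e_vdw = lj_energy(complex_, params)
    try:
        e_elec = coulomb_energy(complex_, params)
    except InputError:
        e_elec = 0.0
    e_desolv = desolvation_energy(complex_) if include_desolv else 0.0
    return pose_score(e_vdw, e_elec, e_desolv, e_air, weights)
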