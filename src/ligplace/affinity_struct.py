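"""Structure-based binding-affinity scoring: contact counts + linear ΔG model.

The predictor counts intermolecular atomic contacts within 10.5 Å between
the protein (including retained waters and hetero groups) and the ligand,
classed by element pair, and combines them with the intermolecular
electrostatic energy in a fixed linear model:

    ΔG_score = 0.343794·E_elec − 0.037597·AC_CC + 0.138738·AC_NN
             + 0.160043·AC_OO − 3.088861·AC_XX + 187.011384

Eligible atoms are heavy atoms plus polar hydrogens; C–C, N–N and O–O
pairs feed their own counts and every other eligible pair lands in AC_XX,
so the four classes are mutually exclusive and exhaustive. Compounds are
ranked by the mean ΔG_score of their 10 best-scoring poses (lower = tighter
binding, the ΔG convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .chem_io import ComplexStructure
from .errors import InputError
from .pose_pipeline import PoseSet

# Fixed coefficients of the linear ΔG model (trained upstream on
# protein–protein interaction affinities; immutable here by design).
DG_COEFF_E_ELEC = 0.343794
DG_COEFF_CC = -0.037597
DG_COEFF_NN = 0.138738
DG_COEFF_OO = 0.160043
DG_COEFF_XX = -3.088861
DG_INTERCEPT = 187.011384

DEFAULT_CONTACT_CUTOFF = 10.5  # Å


@dataclass(frozen=True)
class ContactCounts:
    cc: int
    nn: int
    oo: int
    xx: int

    def __post_init__(self):
        if min(self.cc, self.nn, self.oo, self.xx) < 0:
            raise InputError("contact counts must be non-negative")

    @property
    def total(self) -> int:
        return self.cc + self.nn + self.oo + self.xx


@dataclass(frozen=True)
class AffinityPrediction:
    compound_id: str
    per_pose: tuple[float, ...]
    mean_dg: float
    rank: int = 0


def _eligible(elements, is_heavy, is_polar_h, include_nonpolar_h: bool):
    mask = np.asarray(is_heavy) | np.asarray(is_polar_h)
    if include_nonpolar_h:
        mask = np.ones(len(elements), dtype=bool)
    return mask


def count_contacts(
    complex_: ComplexStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    include_nonpolar_h: bool = False,
) -> ContactCounts:
    """Classed intermolecular contact counts within the distance cutoff.

    Protein-side eligibility uses a nearest-heavy-atom rule to tag polar
    hydrogens (H within bonding distance of N/O/S); the ligand side uses its
    graph-derived flags. Waters and retained hetero groups count on the
    protein side.
    """
    prot = complex_.protein
    lig = complex_.ligand

    prot_polar_h = _protein_polar_h(prot)
    prot_heavy = np.array([el != "H" for el in prot.elements])
    pmask = _eligible(prot.elements, prot_heavy, prot_polar_h, include_nonpolar_h)

    lmask = _eligible(lig.elements, lig.is_heavy, lig.is_polar_hydrogen, include_nonpolar_h)

    pe = [el for el, m in zip(prot.elements, pmask) if m]
    le = [el for el, m in zip(lig.elements, lmask) if m]
    d = cdist(prot.coords[pmask], complex_.ligand_coords()[lmask])
    within = d <= cutoff

    cc = nn = oo = xx = 0
    for i, j in zip(*np.where(within)):
        a, b = pe[i], le[j]
        if a == b == "C":
            cc += 1
        elif a == b == "N":
            nn += 1
        elif a == b == "O":
            oo += 1
        else:
            xx += 1
    return ContactCounts(cc=cc, nn=nn, oo=oo, xx=xx)


def _protein_polar_h(prot) -> np.ndarray:
    flags = np.zeros(prot.n_atoms, dtype=bool)
    h_idx = [i for i, el in enumerate(prot.elements) if el == "H"]
    heavy_idx = [i for i, el in enumerate(prot.elements) if el != "H"]
    if not h_idx or not heavy_idx:
        return flags
    d = cdist(prot.coords[h_idx], prot.coords[heavy_idx])
    for row, i in enumerate(h_idx):
        j = heavy_idx[int(np.argmin(d[row]))]
        if d[row].min() < 1.3 and prot.elements[j] in ("N", "O", "S"):
            flags[i] = True
    return flags


def dG_score(e_elec: float, counts: ContactCounts) -> float:
    """The fixed linear ΔG model evaluated on one pose."""
    if not math.isfinite(e_elec):
        raise InputError("E_elec must be finite")
    return (
        DG_COEFF_E_ELEC * e_elec
        + DG_COEFF_CC * counts.cc
        + DG_COEFF_NN * counts.nn
        + DG_COEFF_OO * counts.oo
        + DG_COEFF_XX * counts.xx
        + DG_INTERCEPT
    )


def score_pose_affinity(
    complex_: ComplexStructure,
    e_elec: float,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    include_nonpolar_h: bool = False,
) -> float:
    return dG_score(
        e_elec, count_contacts(complex_, cutoff=cutoff, include_nonpolar_h=include_nonpolar_h)
    )


def rank_compounds_structural(
    pose_sets: dict[str, PoseSet],
    top_k: int = 10,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[AffinityPrediction]:
    """Rank compounds by the mean ΔG_score of their top-k poses.

    Poses are already score-sorted inside each PoseSet; the k best by pose
    score enter the average. Lower mean = predicted tighter binder; ties
    break deterministically on compound id.
    """
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    preds = []
    for cid, pose_set in pose_sets.items():
        if not pose_set.poses:
            raise InputError(f"compound {cid!r} has no scored poses")
        top = pose_set.poses[:top_k]
        per_pose = tuple(
            score_pose_affinity(cx, report.e_elec, cutoff=cutoff) for cx, report in top
        )
        preds.append(
            AffinityPrediction(
                compound_id=cid, per_pose=per_pose, mean_dg=float(np.mean(per_pose))
            )
        )
    preds.sort(key=lambda p: (p.mean_dg, p.compound_id))
    return [
        AffinityPrediction(
            compound_id=p.compound_id, per_pose=p.per_pose, mean_dg=p.mean_dg, rank=i + 1
        )
        for i, p in enumerate(preds)
    ]
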