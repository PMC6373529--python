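"""Assessment stack: interface-superposed ligand RMSD and ranking metrics.

Models are compared to reference structures by (1) least-squares
superposition on the reference's 5 Å interface protein heavy atoms,
(2) heavy-atom ligand RMSD excluding halogens and hydrogens, minimised
over graph automorphisms so symmetric flips (e.g. a phenyl rotation) do
not inflate the deviation. A pose is of acceptable quality at
RMSD ≤ 2.5 Å; success rates count targets whose best of the first n
submitted models is acceptable. Affinity rankings are scored with
tie-corrected Kendall's tau-b and classifications with the Matthews
correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy import stats

from ._geometry import RigidTransform, kabsch
from .chem_io import ComplexStructure
from .errors import InputError
from .pose_pipeline import interface_residues

MAX_AUTOMORPHISMS = 10000


@dataclass
class EvaluationReport:
    rmsds: dict[str, list[float]]  # target id -> per-model RMSD (submission order)
    threshold: float = 2.5
    tau: float | None = None
    mcc: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def top1_success(self) -> float:
        return success_rates(self.rmsds, threshold=self.threshold, n=1)

    @property
    def top5_success(self) -> float:
        return success_rates(self.rmsds, threshold=self.threshold, n=5)

    def summary(self) -> tuple[float, float]:
        """Mean ± sd over all models of all targets."""
        flat = [r for rs in self.rmsds.values() for r in rs]
        return float(np.mean(flat)), float(np.std(flat))


# ---------------------------------------------------------------------------
# Superposition + RMSD
# ---------------------------------------------------------------------------


def superpose_interface(
    model: ComplexStructure, ref: ComplexStructure, cutoff: float = 5.0
) -> RigidTransform:
    """Optimal rigid fit of the model onto the reference interface.

    Interface = reference protein residues within `cutoff` Å of the
    reference ligand; atoms pair 1:1 by (chain, residue number, atom name)
    over heavy atoms. Kabsch (McLachlan-equivalent) least squares.
    """
    iface = interface_residues(ref, cutoff=cutoff)
    if not iface:
        raise InputError("reference has no interface residues")

    def atom_map(prot):
        return {
            (prot.chains[i], int(prot.resseqs[i]), prot.names[i]): i
            for i in range(prot.n_atoms)
            if prot.elements[i] != "H" and (prot.chains[i], int(prot.resseqs[i])) in iface
        }

    map_ref = atom_map(ref.protein)
    map_mod = atom_map(model.protein)
    common = sorted(set(map_ref) & set(map_mod))
    if len(common) < 3:
        raise InputError(
            f"only {len(common)} paired interface atoms; need at least 3"
        )
    mobile = model.protein.coords[[map_mod[k] for k in common]]
    target = ref.protein.coords[[map_ref[k] for k in common]]
    return kabsch(mobile, target)


def ligand_rmsd(
    model: ComplexStructure,
    ref: ComplexStructure,
    transform: RigidTransform | None = None,
    symmetry_corrected: bool = True,
) -> float:
    """Heavy-atom ligand RMSD (halogens excluded) after an optional transform.

    The transform (typically from :func:`superpose_interface`) is applied to
    the model ligand; no further fitting happens here. With
    `symmetry_corrected` the graph automorphisms of the compound are
    enumerated and the minimum RMSD over equivalent atom mappings returned.
    """
    transform = transform or RigidTransform.identity()

    ref_heavy, ref_idx = _rmsd_subset(ref)
    mod_heavy, mod_idx = _rmsd_subset(model)
    ref_xyz = ref.ligand_coords()[ref_idx]
    mod_xyz = transform.apply(model.ligand_coords()[mod_idx])
    if len(ref_idx) != len(mod_idx):
        raise InputError(
            f"ligand atom-count mismatch after exclusions: {len(mod_idx)} vs {len(ref_idx)}"
        )

    if symmetry_corrected:
        matches = mod_heavy.GetSubstructMatches(
            ref_heavy, uniquify=False, useChirality=False, maxMatches=MAX_AUTOMORPHISMS
        )
    else:
        matches = ()
    if not matches:
        matches = (tuple(range(len(ref_idx))),)

    best = math.inf
    for match in matches:
        # match[k] = model-heavy index matched to reference-heavy atom k
        dev = mod_xyz[list(match)] - ref_xyz
        best = min(best, float(np.sqrt(np.mean(np.sum(dev**2, axis=1)))))
    return best


def _rmsd_subset(complex_: ComplexStructure):
    """RDKit heavy-atom mol (halogens stripped) + original atom indices."""
    lig = complex_.ligand
    keep = lig.is_heavy & ~lig.is_halogen
    idx = np.where(keep)[0]
    if len(idx) == 0:
        raise InputError("no atoms left after heavy/halogen exclusions")
    rw = Chem.RWMol()
    remap = {}
    for new, old in enumerate(idx):
        rw.AddAtom(Chem.Atom(lig.rdkit_mol.GetAtomWithIdx(int(old)).GetSymbol()))
        remap[int(old)] = new
    for b in lig.rdkit_mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            rw.AddBond(remap[i], remap[j], Chem.BondType.SINGLE)
    return rw.GetMol(), idx


def evaluate_pose_sets(
    pose_sets: dict[str, object],
    references: dict[str, ComplexStructure],
    threshold: float = 2.5,
    cutoff: float = 5.0,
) -> EvaluationReport:
    """Score each target's submission against its reference structure."""
    rmsds: dict[str, list[float]] = {}
    for tid, pose_set in pose_sets.items():
        if tid not in references:
            raise InputError(f"no reference structure for target {tid!r}")
        ref = references[tid]
        vals = []
        for model, _ in pose_set.submission:
            t = superpose_interface(model, ref, cutoff=cutoff)
            vals.append(ligand_rmsd(model, ref, transform=t))
        rmsds[tid] = vals
    return EvaluationReport(rmsds=rmsds, threshold=threshold)


# ---------------------------------------------------------------------------
# Summary metrics
# ---------------------------------------------------------------------------


def success_rates(
    rmsds_per_target: dict[str, list[float]], threshold: float = 2.5, n: int = 5
) -> float:
    """Fraction of targets whose best of the first n models is acceptable."""
    if not rmsds_per_target:
        raise InputError("no targets to evaluate")
    hits = 0
    for tid, vals in rmsds_per_target.items():
        if not vals:
            raise InputError(f"target {tid!r} has no models")
        if min(vals[:n]) <= threshold:
            hits += 1
    return hits / len(rmsds_per_target)


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall's tau-b between two equal-length rankings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InputError("kendall_tau needs two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InputError("kendall_tau undefined for an all-tied vector")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def matthews_cc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 by convention if a factor is 0."""
    if min(tp, fp, fn, tn) < 0:
        raise InputError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def confusion_counts(
    truth: dict[str, bool], predicted: dict[str, bool]
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) over the shared compound ids."""
    tp = fp = fn = tn = 0
    for cid in truth:
        if cid not in predicted:
            raise InputError(f"no prediction for compound {cid!r}")
        t, p = truth[cid], predicted[cid]
        tp += t and p
        fp += (not t) and p
        fn += t and (not p)
        tn += (not t) and (not p)
    return tp, fp, fn, tn
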