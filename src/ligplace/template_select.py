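"""Template selection by maximum-common-substructure Tanimoto similarity.

A template is a solved protein–ligand complex; the target compound is
compared to each template's crystallographic ligand on the heavy-atom
graph. Similarity is Tanimoto on the connected MCS atom count:

    sim(A, B) = |MCS| / (n_A + n_B - |MCS|)

with element-exact atom typing and bond-order-insensitive edges (a single
bond may match an aromatic one). The literature sometimes reports the
complementary "Tanimoto distance" = 1 - sim; this module returns the
similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem_io import ComplexStructure, Molecule
from .errors import InputError

logger = logging.getLogger(__name__)

LOW_SIMILARITY_WARN = 0.6


@dataclass
class TemplateRecord:
    """A template complex plus the 2D graph of its bound ligand."""

    id: str
    complex: ComplexStructure
    ligand_2d: Molecule


@dataclass(frozen=True)
class SimilarityResult:
    template_id: str
    similarity: float
    mcs_atom_count: int
    approximate: bool = False  # True when the MCS search hit its time budget


def _heavy(mol: Molecule) -> Chem.Mol:
    m = Chem.RemoveHs(Chem.Mol(mol.rdkit_mol), sanitize=False)
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    return m


def mcs_tanimoto(
    a: Molecule, b: Molecule, timeout_s: int = 10, template_id: str = ""
) -> SimilarityResult:
    """Tanimoto similarity of two molecules via their connected heavy-atom MCS.

    Atoms match on element; bonds match regardless of order. The search is
    atom-count maximising with a time budget; if the budget is hit the
    best-so-far result is returned flagged ``approximate``.
    """
    ha, hb = _heavy(a), _heavy(b)
    na, nb = ha.GetNumAtoms(), hb.GetNumAtoms()
    if na == 0 or nb == 0:
        raise InputError("MCS similarity requires non-empty molecules")

    params = rdFMCS.MCSParameters()
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareAny
    params.MaximizeBonds = False
    params.Timeout = timeout_s
    params.AtomCompareParameters.MatchValences = False
    params.AtomCompareParameters.MatchChiralTag = False
    params.BondCompareParameters.RingMatchesRingOnly = False
    params.BondCompareParameters.CompleteRingsOnly = False

    res = rdFMCS.FindMCS([ha, hb], params)
    mcs = int(res.numAtoms) if res.numAtoms > 0 else 0
    if mcs == 0:
        # FindMCS can report 0 for single-atom overlaps; fall back to the
        # largest shared element (a 1-atom common subgraph is always connected)
        ea = {at.GetSymbol() for at in ha.GetAtoms()}
        eb = {at.GetSymbol() for at in hb.GetAtoms()}
        mcs = 1 if ea & eb else 0
    sim = mcs / (na + nb - mcs) if mcs else 0.0
    return SimilarityResult(
        template_id=template_id,
        similarity=float(sim),
        mcs_atom_count=mcs,
        approximate=bool(res.canceled),
    )


def rank_templates(
    target: Molecule, library: list[TemplateRecord], timeout_s: int = 10
) -> list[SimilarityResult]:
    """Rank a template library by ligand similarity to the target.

    Descending similarity; ties broken by lexicographic template id so the
    ranking is deterministic.
    """
    if not library:
        raise InputError("template library is empty")
    results = [
        mcs_tanimoto(target, rec.ligand_2d, timeout_s=timeout_s, template_id=rec.id)
        for rec in library
    ]
    return sorted(results, key=lambda r: (-r.similarity, r.template_id))


def select_template(
    target: Molecule, library: list[TemplateRecord], timeout_s: int = 10
) -> tuple[TemplateRecord, SimilarityResult]:
    """Pick the single best template for a target compound.

    Low similarity is common in prospective use and is only warned about,
    never fatal.
    """
    ranking = rank_templates(target, library, timeout_s=timeout_s)
    best = ranking[0]
    record = next(rec for rec in library if rec.id == best.template_id)
    if best.similarity < LOW_SIMILARITY_WARN:
        logger.warning(
            "best template %s has low ligand similarity %.3f",
            best.template_id,
            best.similarity,
        )
    else:
        logger.info(
            "selected template %s (similarity %.3f)", best.template_id, best.similarity
        )
    return record, best
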