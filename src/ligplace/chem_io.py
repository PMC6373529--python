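"""Molecule and structure containers plus the standard-format I/O layer.

Small molecules are thin wrappers around RDKit molecules with explicit
hydrogens; protein structures are flat numpy-backed atom tables read and
written through Biopython's PDB machinery. Everything downstream (shape
overlay, energetics, contact counting, evaluation) consumes these types.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdDetermineBonds

from .errors import InputError

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL"}
HALOGENS = {"F", "Cl", "Br", "I"}
_SMILES_ALPHABET = re.compile(r"[A-Za-z0-9@+\-\[\]()=#$:/\\%.*]")


# ---------------------------------------------------------------------------
# Molecule
# ---------------------------------------------------------------------------


class Molecule:
    """A small molecule: chemical graph, optional conformers, atom annotations.

    Wraps an RDKit ``Mol`` with explicit hydrogens. Coordinates live in RDKit
    conformers (Å); ``partial_charges`` holds per-atom charges in elementary
    units once assigned. Atom flags (heavy / polar hydrogen / halogen) are
    derived from the graph and partition the atom set: every atom is exactly
    one of heavy, polar hydrogen, or nonpolar hydrogen.
    """

    def __init__(self, rdkit_mol: Chem.Mol, name: str = ""):
        self.rdkit_mol = rdkit_mol
        self.name = name
        self.partial_charges: np.ndarray | None = None

    # -- basic graph views ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.rdkit_mol.GetNumAtoms()

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.rdkit_mol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.rdkit_mol.GetBonds()
        ]

    @property
    def is_heavy(self) -> np.ndarray:
        return np.array([a.GetAtomicNum() != 1 for a in self.rdkit_mol.GetAtoms()])

    @property
    def is_halogen(self) -> np.ndarray:
        return np.array([a.GetSymbol() in HALOGENS for a in self.rdkit_mol.GetAtoms()])

    @property
    def is_polar_hydrogen(self) -> np.ndarray:
        """Hydrogens bonded to N, O or S."""
        flags = np.zeros(self.n_atoms, dtype=bool)
        for a in self.rdkit_mol.GetAtoms():
            if a.GetAtomicNum() == 1:
                flags[a.GetIdx()] = any(
                    nb.GetSymbol() in ("N", "O", "S") for nb in a.GetNeighbors()
                )
        return flags

    # -- conformers ----------------------------------------------------------

    @property
    def n_conformers(self) -> int:
        return self.rdkit_mol.GetNumConformers()

    def coords(self, conf_id: int = 0) -> np.ndarray:
        if self.n_conformers == 0:
            raise InputError(f"molecule {self.name!r} has no 3D coordinates")
        return np.array(self.rdkit_mol.GetConformer(conf_id).GetPositions())

    def set_coords(self, coords: np.ndarray, conf_id: int = 0) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise InputError(
                f"coordinate shape {coords.shape} does not match {self.n_atoms} atoms"
            )
        if self.n_conformers == 0:
            conf = Chem.Conformer(self.n_atoms)
            self.rdkit_mol.AddConformer(conf, assignId=True)
        conf = self.rdkit_mol.GetConformer(conf_id)
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))

    def copy(self) -> "Molecule":
        out = Molecule(Chem.Mol(self.rdkit_mol), name=self.name)
        if self.partial_charges is not None:
            out.partial_charges = self.partial_charges.copy()
        return out

    def heavy_coords(self, conf_id: int = 0) -> np.ndarray:
        return self.coords(conf_id)[self.is_heavy]

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(self.rdkit_mol)))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Molecule({self.canonical_smiles()!r}, atoms={self.n_atoms}, "
            f"conformers={self.n_conformers})"
        )


# ---------------------------------------------------------------------------
# Protein / complex containers
# ---------------------------------------------------------------------------


@dataclass
class ProteinStructure:
    """Flat atom table for the polymer (plus tagged waters / hetero groups)."""

    elements: list[str]
    names: list[str]
    resnames: list[str]
    resseqs: np.ndarray  # int, 1-based as in the source file
    chains: list[str]
    coords: np.ndarray  # (n, 3) Å
    is_water: np.ndarray  # bool
    is_hetero: np.ndarray  # bool (non-water hetero groups, e.g. DMSO, SO4)
    charges: np.ndarray | None = None  # elementary units

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.resseqs = np.asarray(self.resseqs, dtype=int)
        self.is_water = np.asarray(self.is_water, dtype=bool)
        self.is_hetero = np.asarray(self.is_hetero, dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise InputError("protein coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resseq) keys in file order."""
        seen: dict[tuple[str, int], None] = {}
        for ch, rs in zip(self.chains, self.resseqs):
            seen.setdefault((ch, int(rs)), None)
        return list(seen)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, transform) -> "ProteinStructure":
        out = ProteinStructure(
            elements=list(self.elements),
            names=list(self.names),
            resnames=list(self.resnames),
            resseqs=self.resseqs.copy(),
            chains=list(self.chains),
            coords=transform.apply(self.coords),
            is_water=self.is_water.copy(),
            is_hetero=self.is_hetero.copy(),
            charges=None if self.charges is None else self.charges.copy(),
        )
        return out


@dataclass
class ComplexStructure:
    """One protein plus one ligand pose in a shared coordinate frame."""

    protein: ProteinStructure
    ligand: Molecule
    conf_id: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ligand.n_conformers == 0:
            raise InputError("complex ligand must carry 3D coordinates")

    def ligand_coords(self) -> np.ndarray:
        return self.ligand.coords(self.conf_id)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_smiles(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string into a Molecule with explicit hydrogens.

    No coordinates are generated; conformers come later. On failure the error
    reports the position of the first offending token when it can be located.
    """
    text = text.strip()
    if not text:
        raise InputError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        for pos, ch in enumerate(text):
            if not _SMILES_ALPHABET.match(ch):
                raise InputError(
                    f"SMILES parse failure in {text!r}: unexpected token {ch!r} "
                    f"at position {pos}"
                )
        # all characters legal individually -> structural error; bisect for locus
        pos = _first_bad_prefix(text)
        raise InputError(f"SMILES parse failure in {text!r} near position {pos}")
    mol = Chem.AddHs(mol)
    return Molecule(mol, name=name or text)


def _first_bad_prefix(text: str) -> int:
    """Best-effort position of the first prefix that can never be completed."""
    for i in range(1, len(text) + 1):
        frag = text[:i]
        if Chem.MolFromSmiles(frag, sanitize=False) is None and not any(
            c in frag for c in "([%"
        ):
            return i - 1
    return len(text) - 1


def molecule_from_atoms(
    elements: list[str], coords: np.ndarray, name: str = "", charge: int = 0
) -> Molecule:
    """Build a Molecule from bare elements + coordinates, inferring bonds.

    Used for hetero groups read from PDB files, which carry no connectivity.
    """
    rw = Chem.RWMol()
    for el in elements:
        rw.AddAtom(Chem.Atom(el))
    conf = Chem.Conformer(len(elements))
    for i, xyz in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineConnectivity(mol, charge=charge)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
        )
    except Exception:
        logger.warning("bond perception failed for %s; keeping bare atoms", name)
    return Molecule(mol, name=name)


def read_pdb_complex(path, ligand_resname: str) -> ComplexStructure:
    """Read a PDB file and split it into protein + the named hetero ligand.

    Waters and other hetero groups stay on the protein side, tagged. If the
    ligand residue occurs more than once, the copy nearest the protein
    centroid is chosen and a warning is emitted. Altloc ambiguity resolves to
    the highest-occupancy conformer (first on ties).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())

    prot_rows: list[tuple] = []
    ligand_copies: list[tuple[list[str], list[np.ndarray], tuple]] = []

    for chain in model:
        for residue in chain:
            hetfield, resseq, _ = residue.id
            resname = residue.get_resname().strip()
            is_water = hetfield == "W" or resname in WATER_RESNAMES
            is_het = hetfield.startswith("H_")
            atoms = _dedup_altlocs(residue.get_unpacked_list())
            if is_het and resname == ligand_resname:
                els = [_element_of(a) for a in atoms]
                xyz = [np.array(a.get_coord(), dtype=float) for a in atoms]
                ligand_copies.append((els, xyz, (chain.id, resseq)))
                continue
            for atom in atoms:
                prot_rows.append(
                    (
                        _element_of(atom),
                        atom.get_name(),
                        resname,
                        int(resseq),
                        chain.id,
                        np.array(atom.get_coord(), dtype=float),
                        is_water,
                        is_het,
                    )
                )

    if not ligand_copies:
        raise InputError(f"no such hetero group {ligand_resname!r} in {path}")
    if not prot_rows:
        raise InputError(f"no protein atoms in {path}")

    protein = ProteinStructure(
        elements=[r[0] for r in prot_rows],
        names=[r[1] for r in prot_rows],
        resnames=[r[2] for r in prot_rows],
        resseqs=np.array([r[3] for r in prot_rows]),
        chains=[r[4] for r in prot_rows],
        coords=np.array([r[5] for r in prot_rows]),
        is_water=np.array([r[6] for r in prot_rows]),
        is_hetero=np.array([r[7] for r in prot_rows]),
    )

    if len(ligand_copies) > 1:
        centroid = protein.coords[~protein.is_water & ~protein.is_hetero].mean(axis=0)
        dists = [
            np.linalg.norm(np.mean(xyz, axis=0) - centroid)
            for _, xyz, _ in ligand_copies
        ]
        pick = int(np.argmin(dists))
        warnings.warn(
            f"{len(ligand_copies)} copies of {ligand_resname} in {path.name}; "
            f"keeping the copy nearest the protein centroid "
            f"(chain {ligand_copies[pick][2][0]}, residue {ligand_copies[pick][2][1]})",
            stacklevel=2,
        )
    else:
        pick = 0

    els, xyz, _ = ligand_copies[pick]
    ligand = molecule_from_atoms(els, np.array(xyz), name=ligand_resname)
    return ComplexStructure(
        protein=protein, ligand=ligand, provenance={"source": str(path)}
    )


def _dedup_altlocs(atoms):
    """Keep one atom per name: highest occupancy, first on ties."""
    best: dict[str, object] = {}
    order: list[str] = []
    for a in atoms:
        name = a.get_name()
        if name not in best:
            best[name] = a
            order.append(name)
        else:
            if (a.get_occupancy() or 0.0) > (best[name].get_occupancy() or 0.0):
                best[name] = a
    return [best[n] for n in order]


def _element_of(atom) -> str:
    el = (atom.element or "").strip()
    if not el:
        el = re.sub(r"[^A-Za-z]", "", atom.get_name())[:1]
    return el.capitalize()


# ---------------------------------------------------------------------------
# Partial charges
# ---------------------------------------------------------------------------

_GASTEIGER_ELEMENTS = {
    "H", "C", "N", "O", "F", "Cl", "Br", "I", "S", "P", "B", "Si", "Al",
}


def assign_partial_charges(mol: Molecule) -> Molecule:
    """Gasteiger electronegativity-equalization partial charges.

    Deterministic and parameter-light; the total charge matches the formal
    net charge to 1e-3. Returns a new Molecule with ``partial_charges`` set.
    """
    for a in mol.rdkit_mol.GetAtoms():
        if a.GetSymbol() not in _GASTEIGER_ELEMENTS:
            raise InputError(
                f"no charge parameters for element {a.GetSymbol()!r}"
            )
    out = mol.copy()
    AllChem.ComputeGasteigerCharges(out.rdkit_mol, throwOnParamFailure=True)
    q = np.array(
        [
            float(a.GetProp("_GasteigerCharge")) + float(a.GetProp("_GasteigerHCharge"))
            if a.HasProp("_GasteigerHCharge")
            else float(a.GetProp("_GasteigerCharge"))
            for a in out.rdkit_mol.GetAtoms()
        ]
    )
    if not np.all(np.isfinite(q)):
        bad = out.elements[int(np.argmax(~np.isfinite(q)))]
        raise InputError(f"charge assignment failed on element {bad!r}")
    formal = float(Chem.GetFormalCharge(out.rdkit_mol))
    # Gasteiger distributes the formal charge; enforce exact neutrality budget
    drift = formal - q.sum()
    if abs(drift) > 1e-3:
        q += drift / len(q)
    out.partial_charges = q
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_pose_pdb(complex_: ComplexStructure, path, remarks: list[str] | None = None):
    """Write a protein–ligand complex as a PDB file.

    Protein atoms go out as ATOM records (HETATM for waters / tagged hetero
    groups, waters as HOH); the ligand is a single LIG hetero residue. A
    round-trip read reproduces coordinates to the fixed-width 1e-3 Å.
    """
    if complex_.ligand.n_atoms == 0:
        raise InputError("refusing to write a complex with an empty ligand")
    lig_xyz = complex_.ligand_coords()
    all_xyz = np.vstack([complex_.protein.coords, lig_xyz])
    if not np.all(np.isfinite(all_xyz)):
        raise InputError("non-finite coordinates")
    if np.any(np.abs(all_xyz) > 9999.999):
        raise InputError("coordinates exceed PDB fixed-width limit (9999.999 Å)")

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("pose")
    builder.init_model(0)
    builder.init_seg("    ")

    prot = complex_.protein
    current = None
    serial = 1
    for i in range(prot.n_atoms):
        chain_id = prot.chains[i]
        resseq = int(prot.resseqs[i])
        resname = "HOH" if prot.is_water[i] else prot.resnames[i]
        hetfield = "W" if prot.is_water[i] else ("H_" + resname if prot.is_hetero[i] else " ")
        key = (chain_id, hetfield, resseq)
        if key != current:
            if current is None or chain_id != current[0]:
                builder.init_chain(chain_id)
            builder.init_residue(resname, hetfield, resseq, " ")
            current = key
        builder.init_atom(
            _unique_name(prot.names[i]),
            prot.coords[i].astype(float),
            1.0,
            1.0,
            " ",
            _pad_name(prot.names[i]),
            serial,
            element=prot.elements[i].upper(),
        )
        serial += 1

    builder.init_chain("Z")
    builder.init_residue("LIG", "H_LIG", 1, " ")
    counts: dict[str, int] = {}
    for i, el in enumerate(complex_.ligand.elements):
        counts[el] = counts.get(el, 0) + 1
        name = f"{el.upper()}{counts[el]}"
        builder.init_atom(
            name, lig_xyz[i].astype(float), 1.0, 1.0, " ", _pad_name(name),
            serial, element=el.upper(),
        )
        serial += 1

    io = PDBIO()
    io.set_structure(builder.get_structure())
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    io.save(str(path))
    if remarks:
        text = path.read_text()
        header = "".join(f"REMARK   3 {r}\n" for r in remarks)
        path.write_text(header + text)
    return path


def _pad_name(name: str) -> str:
    return name if len(name) >= 4 else f" {name:<3s}"


def _unique_name(name: str) -> str:
    return name


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------


def read_sdf(path) -> list[Molecule]:
    """Read all molecules from a V2000 SDF file (hydrogens kept explicit)."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise InputError(f"unreadable SDF record {i} in {path}")
        out.append(Molecule(Chem.AddHs(mol, addCoords=True), name=mol.GetProp("_Name") or f"mol{i}"))
    if not out:
        raise InputError(f"no molecules in {path}")
    return out


def write_sdf(mols: list[Molecule], path) -> None:
    """Write molecules (all conformers of each) to a V2000 SDF file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for m in mols:
        m.rdkit_mol.SetProp("_Name", m.name)
        if m.n_conformers == 0:
            raise InputError(f"molecule {m.name!r} has no coordinates to write")
        for conf in m.rdkit_mol.GetConformers():
            writer.write(m.rdkit_mol, confId=conf.GetId())
    writer.close()
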