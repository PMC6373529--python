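import numpy as np
import pytest
from hypothesis import settings

from ligplace.synthetic_fixtures import FixtureSpec, make_pocket_complex

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

POCKET_SEED = 1


@pytest.fixture(scope="session")
def pocket():
    """Equilibrated moulded pocket with its planted truth pose (shared)."""
    spec = FixtureSpec(seed=POCKET_SEED)
    complex_, truth = make_pocket_complex(spec)
    return spec, complex_, truth


@pytest.fixture(scope="session")
def cheap_pocket():
    """Un-equilibrated pocket: fast geometry-only fixture."""
    spec = FixtureSpec(seed=0, equilibrate=False)
    complex_, truth = make_pocket_complex(spec)
    return spec, complex_, truth


@pytest.fixture()
def single_atom_complex_factory():
    """Build minimal complexes from explicit atom lists (for energetics)."""

    def build(protein_atoms, ligand_atoms, protein_charges=None, ligand_charges=None):
        from ligplace.chem_io import ComplexStructure, ProteinStructure, molecule_from_atoms

        p_el = [a[0] for a in protein_atoms]
        p_xyz = np.array([a[1] for a in protein_atoms], dtype=float)
        protein = ProteinStructure(
            elements=p_el,
            names=[f"{el.upper()}{i + 1}" for i, el in enumerate(p_el)],
            resnames=["GLY"] * len(p_el),
            resseqs=np.arange(1, len(p_el) + 1),
            chains=["A"] * len(p_el),
            coords=p_xyz,
            is_water=np.zeros(len(p_el), dtype=bool),
            is_hetero=np.zeros(len(p_el), dtype=bool),
            charges=None if protein_charges is None else np.asarray(protein_charges, float),
        )
        l_el = [a[0] for a in ligand_atoms]
        l_xyz = np.array([a[1] for a in ligand_atoms], dtype=float)
        ligand = molecule_from_atoms(l_el, l_xyz, name="toy-ligand")
        if ligand_charges is not None:
            ligand.partial_charges = np.asarray(ligand_charges, dtype=float)
        return ComplexStructure(protein=protein, ligand=ligand)

    return build


def write_toy_pdb(path, residues):
    """Write a minimal fixed-width PDB from (record, name, resname, chain,
    resseq, xyz, element, occupancy) tuples."""
    lines = []
    for i, (rec, name, resname, chain, resseq, xyz, el, occ, altloc) in enumerate(residues):
        lines.append(
            f"{rec:<6s}{i + 1:>5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}  0.00          {el:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
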