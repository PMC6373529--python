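import numpy as np
import pytest

import ligplace as lp
from conftest import write_toy_pdb
from ligplace.chem_io import molecule_from_atoms
from ligplace.errors import InputError


@pytest.mark.parametrize(
    "smiles, n_heavy, n_h, n_polar_h, n_halogen",
    [
        ("CCO", 3, 6, 1, 0),        # ethanol: one O–H polar hydrogen
        ("c1ccccc1", 6, 6, 0, 0),   # benzene: aromatic, no polar hydrogens
        ("OC(=O)C(F)(F)F", 7, 1, 1, 3),  # TFA: three fluorines flagged
        ("CS", 2, 4, 1, 0),         # methanethiol: S–H counts as polar
    ],
)
def test_smiles_atom_flags(smiles, n_heavy, n_h, n_polar_h, n_halogen):
    mol = lp.read_smiles(smiles)
    assert int(mol.is_heavy.sum()) == n_heavy
    assert mol.n_atoms - n_heavy == n_h
    assert int(mol.is_polar_hydrogen.sum()) == n_polar_h
    assert int(mol.is_halogen.sum()) == n_halogen


@pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "OC(=O)C(F)(F)F", "CC(N)C(=O)O"])
def test_atom_flags_partition(smiles):
    """Every atom is exactly one of heavy / polar H / nonpolar H."""
    mol = lp.read_smiles(smiles)
    heavy = mol.is_heavy
    polar_h = mol.is_polar_hydrogen
    nonpolar_h = ~heavy & ~polar_h
    combined = heavy.astype(int) + polar_h.astype(int) + nonpolar_h.astype(int)
    assert np.all(combined == 1)
    assert not np.any(heavy & polar_h)


@pytest.mark.parametrize("smiles", ["CCO", "CC(=O)[O-]", "c1ccc2ccccc2c1", "CN1C=NC=C1"])
def test_smiles_round_trip_preserves_composition(smiles):
    mol = lp.read_smiles(smiles)
    again = lp.read_smiles(mol.canonical_smiles())
    assert sorted(mol.elements) == sorted(again.elements)
    assert int(mol.is_heavy.sum()) == int(again.is_heavy.sum())


def test_bad_smiles_reports_position():
    with pytest.raises(InputError, match="position"):
        lp.read_smiles("CC!O")
    with pytest.raises(InputError):
        lp.read_smiles("C(C")


@pytest.mark.parametrize(
    "smiles, expected_sum",
    [("C", 0.0), ("CC(=O)[O-]", -1.0), ("O", 0.0)],
)
def test_partial_charges_sum_to_formal_charge(smiles, expected_sum):
    mol = lp.assign_partial_charges(lp.read_smiles(smiles))
    assert mol.partial_charges.sum() == pytest.approx(expected_sum, abs=1e-3)


def test_water_charge_signs():
    """Electronegativity equalization puts negative charge on oxygen."""
    mol = lp.assign_partial_charges(lp.read_smiles("O"))
    q = dict(zip(mol.elements, mol.partial_charges))
    assert q["O"] < 0
    assert all(qi > 0 for el, qi in zip(mol.elements, mol.partial_charges) if el == "H")


def test_unsupported_element_rejected():
    with pytest.raises(InputError, match="Fe"):
        lp.assign_partial_charges(lp.read_smiles("[Fe]"))


def _toy_rows(lig_center, resseq=1, chain="B"):
    return [
        ("HETATM", "C1", "LIG", chain, resseq, np.array(lig_center), "C", 1.0, " "),
        ("HETATM", "O1", "LIG", chain, resseq, np.array(lig_center) + [1.3, 0, 0], "O", 1.0, " "),
    ]


def _protein_rows():
    rows = []
    for i, x in enumerate([0.0, 3.0, 6.0]):
        rows.append(("ATOM", "N", "GLY", "A", i + 1, np.array([x, 0.0, 0.0]), "N", 1.0, " "))
        rows.append(("ATOM", "CA", "GLY", "A", i + 1, np.array([x, 1.4, 0.0]), "C", 1.0, " "))
    return rows


def test_read_pdb_complex_splits_ligand(tmp_path):
    path = write_toy_pdb(tmp_path / "toy.pdb", _protein_rows() + _toy_rows([3.0, 4.0, 0.0]))
    cx = lp.read_pdb_complex(path, "LIG")
    assert cx.protein.n_atoms == 6
    assert cx.ligand.n_atoms == 2
    assert sorted(cx.ligand.elements) == ["C", "O"]


def test_read_pdb_missing_ligand_errors(tmp_path):
    path = write_toy_pdb(tmp_path / "toy.pdb", _protein_rows())
    with pytest.raises(InputError, match="no such hetero group"):
        lp.read_pdb_complex(path, "LIG")


def test_read_pdb_multiple_ligand_copies_picks_nearest(tmp_path):
    rows = (
        _protein_rows()
        + _toy_rows([3.0, 4.0, 0.0], resseq=1, chain="B")
        + _toy_rows([50.0, 50.0, 50.0], resseq=2, chain="C")
    )
    path = write_toy_pdb(tmp_path / "two.pdb", rows)
    with pytest.warns(UserWarning, match="copies"):
        cx = lp.read_pdb_complex(path, "LIG")
    assert np.linalg.norm(cx.ligand_coords().mean(axis=0)) < 10


def test_read_pdb_waters_tagged(tmp_path):
    rows = _protein_rows() + [
        ("HETATM", "O", "HOH", "W", 1, np.array([8.0, 0.0, 0.0]), "O", 1.0, " ")
    ] + _toy_rows([3.0, 4.0, 0.0])
    cx = lp.read_pdb_complex(write_toy_pdb(tmp_path / "w.pdb", rows), "LIG")
    assert cx.protein.is_water.sum() == 1


def test_altloc_keeps_highest_occupancy(tmp_path):
    rows = [
        ("ATOM", "N", "GLY", "A", 1, np.array([0.0, 0.0, 0.0]), "N", 0.3, "A"),
        ("ATOM", "N", "GLY", "A", 1, np.array([5.0, 0.0, 0.0]), "N", 0.7, "B"),
        ("ATOM", "CA", "GLY", "A", 1, np.array([1.0, 1.4, 0.0]), "C", 1.0, " "),
        ("ATOM", "C", "GLY", "A", 1, np.array([2.0, 1.4, 0.0]), "C", 1.0, " "),
    ] + _toy_rows([2.0, 3.0, 0.0])
    cx = lp.read_pdb_complex(write_toy_pdb(tmp_path / "alt.pdb", rows), "LIG")
    n_idx = cx.protein.names.index("N")
    assert cx.protein.coords[n_idx][0] == pytest.approx(5.0, abs=1e-3)


def test_pdb_write_read_round_trip(tmp_path, cheap_pocket):
    _, cx, _ = cheap_pocket
    path = tmp_path / "pose.pdb"
    lp.write_pose_pdb(cx, path)
    back = lp.read_pdb_complex(path, "LIG")
    assert back.protein.n_atoms == cx.protein.n_atoms
    assert np.abs(back.protein.coords - cx.protein.coords).max() < 1e-3
    assert np.abs(back.ligand_coords() - cx.ligand_coords()).max() < 1e-3
    # idempotent after the first write
    path2 = tmp_path / "pose2.pdb"
    lp.write_pose_pdb(back, path2)
    back2 = lp.read_pdb_complex(path2, "LIG")
    assert np.abs(back2.protein.coords - back.protein.coords).max() < 1e-6


def test_pdb_write_overflow_and_empty_errors(tmp_path, cheap_pocket):
    _, cx, _ = cheap_pocket
    shifted = cx.ligand.copy()
    shifted.set_coords(cx.ligand_coords() + 20000.0)
    from ligplace.chem_io import ComplexStructure

    bad = ComplexStructure(protein=cx.protein, ligand=shifted)
    with pytest.raises(InputError, match="9999"):
        lp.write_pose_pdb(bad, tmp_path / "x.pdb")


def test_sdf_round_trip(tmp_path):
    mol = lp.generate_conformers(lp.read_smiles("CCO"), max_confs=1, seed=1).molecule
    lp.write_sdf([mol], tmp_path / "m.sdf")
    back = lp.read_sdf(tmp_path / "m.sdf")[0]
    assert back.n_atoms == mol.n_atoms
    assert np.abs(back.coords() - mol.coords()).max() < 1e-3


def test_molecule_from_atoms_infers_bonds():
    mol = molecule_from_atoms(["C", "O"], np.array([[0.0, 0, 0], [1.3, 0, 0]]))
    assert len(mol.bonds) == 1
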