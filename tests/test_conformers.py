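import numpy as np
import pytest
from rdkit.Chem import rdMolTransforms

import ligplace as lp
from ligplace._geometry import RigidTransform, random_rotation
from ligplace.conformers import (
    KAPPA,
    PREFACTOR,
    VDW_RADII,
    color_tanimoto_features,
    feature_points,
    gaussian_overlap_volume,
)
from ligplace.errors import InputError
from oracles import gaussian_overlap_grid


@pytest.fixture(scope="module")
def naphthalene_conf():
    return lp.generate_conformers(lp.read_smiles("c1ccc2ccccc2c1"), max_confs=5, seed=7).molecule


def test_rigid_molecule_single_conformer():
    ens = lp.generate_conformers(lp.read_smiles("c1ccccc1"), max_confs=30, seed=1)
    assert ens.n_conformers == 1


def test_butane_samples_anti_and_gauche():
    """The C–C–C–C torsion populates both the anti and gauche wells."""
    ens = lp.generate_conformers(lp.read_smiles("CCCC"), max_confs=100, seed=3)
    mol = ens.molecule.rdkit_mol
    carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    dihedrals = [
        abs(rdMolTransforms.GetDihedralDeg(mol.GetConformer(c.GetId()), *carbons))
        for c in mol.GetConformers()
    ]
    assert any(d > 150 for d in dihedrals), dihedrals
    assert any(40 < d < 80 for d in dihedrals), dihedrals


def test_max_confs_cap_respected():
    ens = lp.generate_conformers(lp.read_smiles("CCCCCCO"), max_confs=3, seed=1)
    assert 1 <= ens.n_conformers <= 3


def test_generation_deterministic_for_seed():
    a = lp.generate_conformers(lp.read_smiles("CCCCO"), max_confs=10, seed=11)
    b = lp.generate_conformers(lp.read_smiles("CCCCO"), max_confs=10, seed=11)
    assert a.n_conformers == b.n_conformers
    for i in range(a.n_conformers):
        assert np.array_equal(a.molecule.coords(i), b.molecule.coords(i))


def test_shape_tanimoto_self_is_one(naphthalene_conf):
    assert lp.shape_tanimoto(naphthalene_conf, naphthalene_conf) == pytest.approx(1.0)


def test_two_atom_shape_closed_form_and_decay():
    """Single-atom 'molecules' at distance d: closed-form Tanimoto, monotone
    decay to 0, exact 1 at d = 0."""
    from ligplace.chem_io import molecule_from_atoms

    def pair_tanimoto(d):
        a = molecule_from_atoms(["C"], np.array([[0.0, 0.0, 0.0]]))
        b = molecule_from_atoms(["C"], np.array([[d, 0.0, 0.0]]))
        return lp.shape_tanimoto(a, b)

    alpha = KAPPA / VDW_RADII["C"] ** 2
    for d in [0.0, 0.5, 1.0, 2.0]:
        # V_AB / (2 V_AA - V_AB) with V_AB = V_AA * exp(-alpha d² / 2)
        g = np.exp(-alpha * d * d / 2.0)
        assert pair_tanimoto(d) == pytest.approx(g / (2 - g), rel=1e-9)
    values = [pair_tanimoto(d) for d in [0.0, 1.0, 2.0, 4.0, 8.0]]
    assert all(x > y for x, y in zip(values, values[1:]))
    assert values[-1] < 1e-6


def test_gaussian_overlap_matches_grid_integration():
    """Analytic pairwise overlap equals brute numerical 3D integration."""
    xa = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
    xb = np.array([[0.7, 0.4, 0.0]])
    aa = KAPPA / np.array([1.70, 1.55]) ** 2
    ab = KAPPA / np.array([1.52]) ** 2
    analytic = gaussian_overlap_volume(xa, aa, xb, ab)
    numeric = gaussian_overlap_grid(xa, aa, xb, ab, PREFACTOR)
    assert analytic == pytest.approx(numeric, rel=2e-3)


def test_self_volume_matches_hard_sphere():
    """Gaussian width calibration: self-overlap of one atom ≈ 4/3 π r³."""
    r = VDW_RADII["C"]
    x = np.array([[0.0, 0.0, 0.0]])
    alpha = np.array([KAPPA / r**2])
    self_volume = gaussian_overlap_volume(x, alpha, x, alpha)
    assert self_volume == pytest.approx(4.0 / 3.0 * np.pi * r**3, rel=0.05)


def test_color_self_is_one_disjoint_is_zero(naphthalene_conf):
    assert lp.color_tanimoto(naphthalene_conf, naphthalene_conf) == pytest.approx(1.0)
    donors = {"donor": np.array([[0.0, 0.0, 0.0]])}
    acceptors = {"acceptor": np.array([[0.0, 0.0, 0.0]])}
    assert color_tanimoto_features(donors, acceptors) == 0.0
    assert color_tanimoto_features({}, {}) == 0.0


def test_hydrocarbon_features_hydrophobe_only():
    ens = lp.generate_conformers(lp.read_smiles("CCCC"), max_confs=1, seed=1)
    feats = feature_points(ens.molecule)
    assert set(feats) == {"hydrophobe"}
    assert len(feats["hydrophobe"]) == 4


def test_overlay_recovers_rigid_motion(naphthalene_conf):
    rng = np.random.default_rng(5)
    g = RigidTransform(random_rotation(rng), np.array([5.0, 5.0, 5.0]))
    moved = naphthalene_conf.copy()
    moved.set_coords(g.apply(moved.coords()))
    ov = lp.overlay(moved, naphthalene_conf)
    assert ov.shape_tanimoto >= 0.99
    assert ov.combo >= 1.98


def test_overlay_beats_random_rotation_oracle():
    """The optimized overlay lands in the top 1% of 1000 random rigid starts."""
    ens = lp.generate_conformers(lp.read_smiles("CCc1ccccc1O"), max_confs=5, seed=2)
    ref = lp.generate_conformers(lp.read_smiles("Cc1ccc(O)cc1"), max_confs=1, seed=2).molecule
    mol = ens.molecule
    ov = lp.overlay(mol, ref)

    xm = mol.heavy_coords(0)
    xr = ref.heavy_coords(0)
    rng = np.random.default_rng(0)
    combos = []
    for _ in range(1000):
        rot = random_rotation(rng)
        trial = mol.copy()
        centered = xm - xm.mean(axis=0)
        placed = centered @ rot.T + xr.mean(axis=0)
        full = mol.coords(0) - xm.mean(axis=0)
        trial.set_coords(full @ rot.T + xr.mean(axis=0))
        combos.append(lp.shape_tanimoto(trial, ref) + lp.color_tanimoto(trial, ref))
    assert ov.combo >= np.quantile(combos, 0.99)


def test_overlay_equivariant_under_rigid_motion(naphthalene_conf):
    ref = lp.generate_conformers(lp.read_smiles("Cc1ccccc1"), max_confs=1, seed=4).molecule
    base = lp.overlay(naphthalene_conf, ref)
    rng = np.random.default_rng(9)
    g = RigidTransform(random_rotation(rng), rng.normal(scale=4.0, size=3))
    moved = naphthalene_conf.copy()
    moved.set_coords(g.apply(moved.coords()))
    again = lp.overlay(moved, ref)
    assert again.combo == pytest.approx(base.combo, abs=1e-6)


def test_select_top_conformers_exact_copy_first(pocket):
    _, cx, _ = pocket
    ens = lp.generate_conformers(lp.read_smiles("c1ccc2ccccc2c1"), max_confs=5, seed=1)
    selected = lp.select_top_conformers(ens, cx.ligand, k=10)
    assert len(selected) == min(10, ens.n_conformers)
    combos = [ov.combo for _, ov in selected]
    assert combos == sorted(combos, reverse=True)
    # top conformer sits on the reference
    top, ov = selected[0]
    assert ov.shape_tanimoto >= 0.98


def test_select_top_order_independent():
    ens = lp.generate_conformers(lp.read_smiles("CCCCO"), max_confs=8, seed=6)
    ref = lp.generate_conformers(lp.read_smiles("CCCO"), max_confs=1, seed=6).molecule
    first = lp.select_top_conformers(ens, ref, k=3)
    # scramble conformer order
    import rdkit.Chem as Chem

    scrambled_mol = Chem.Mol(ens.molecule.rdkit_mol)
    scrambled_mol.RemoveAllConformers()
    order = list(range(ens.n_conformers))[::-1]
    for new_id, i in enumerate(order):
        conf = Chem.Conformer(ens.molecule.rdkit_mol.GetConformer(i))
        conf.SetId(new_id)
        scrambled_mol.AddConformer(conf, assignId=False)
    from ligplace.conformers import ConformerEnsemble
    from ligplace.chem_io import Molecule

    scrambled = ConformerEnsemble(
        molecule=Molecule(scrambled_mol, name="s"),
        energies=[ens.energies[i] for i in order],
    )
    second = lp.select_top_conformers(scrambled, ref, k=3)
    for (m1, o1), (m2, o2) in zip(first, second):
        assert o1.combo == pytest.approx(o2.combo, abs=1e-9)
        assert np.allclose(m1.coords(), m2.coords(), atol=1e-6)


def test_empty_heavy_set_rejected():
    from ligplace.chem_io import molecule_from_atoms

    h_only = molecule_from_atoms(["H"], np.array([[0.0, 0.0, 0.0]]))
    other = molecule_from_atoms(["C"], np.array([[0.0, 0.0, 0.0]]))
    with pytest.raises(InputError):
        lp.shape_tanimoto(h_only, other)
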