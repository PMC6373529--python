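import numpy as np
import pytest

import ligplace as lp
from ligplace._geometry import RigidTransform, kabsch, random_rotation, rmsd
from ligplace.chem_io import ComplexStructure
from ligplace.errors import InputError
from ligplace.evaluation import confusion_counts
from oracles import best_rotation_rmsd_oracle


def _moved_copy(cx, transform):
    lig = cx.ligand.copy()
    lig.set_coords(transform.apply(cx.ligand_coords()))
    return ComplexStructure(protein=cx.protein.transformed(transform), ligand=lig)


def test_superpose_identity(cheap_pocket):
    _, cx, _ = cheap_pocket
    t = lp.superpose_interface(cx, cx)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(t.translation, 0.0, atol=1e-9)


def test_superpose_inverts_rigid_motion(cheap_pocket):
    _, cx, _ = cheap_pocket
    rng = np.random.default_rng(3)
    g = RigidTransform(random_rotation(rng), np.array([4.0, -1.0, 2.0]))
    moved = _moved_copy(cx, g)
    t = lp.superpose_interface(moved, cx)
    recovered = t.apply(moved.protein.coords)
    assert np.abs(recovered - cx.protein.coords).max() < 1e-6


def test_kabsch_beats_random_rotation_oracle():
    rng = np.random.default_rng(0)
    mobile = rng.normal(size=(12, 3)) * 3
    target = rng.normal(size=(12, 3)) * 3
    fit = kabsch(mobile, target)
    fitted = rmsd(fit.apply(mobile), target)
    oracle = best_rotation_rmsd_oracle(mobile, target, n_rotations=10000, seed=1)
    assert fitted <= oracle + 1e-9


def test_superpose_needs_three_atoms(single_atom_complex_factory):
    cx = single_atom_complex_factory([("C", [1.0, 0, 0])], [("C", [0.0, 0.0, 0.0])])
    with pytest.raises(InputError):
        lp.superpose_interface(cx, cx)


def test_ligand_rmsd_zero_and_uniform_shift(cheap_pocket):
    _, cx, _ = cheap_pocket
    assert lp.ligand_rmsd(cx, cx) == pytest.approx(0.0, abs=1e-12)
    shifted = _moved_copy(cx, RigidTransform(np.eye(3), np.array([2.0, 0.0, 0.0])))
    assert lp.ligand_rmsd(shifted, cx) == pytest.approx(2.0, abs=1e-9)


def test_benzene_ring_flip_rmsd_zero_with_symmetry():
    """An in-plane 60° ring rotation is a graph automorphism: corrected RMSD
    is ~0 while the strict-order RMSD is large."""
    mol = lp.generate_conformers(lp.read_smiles("c1ccccc1"), max_confs=1, seed=1).molecule
    from ligplace.chem_io import ProteinStructure

    protein = ProteinStructure(
        elements=["C", "C", "C"], names=["CA", "CB", "CG"], resnames=["GLY"] * 3,
        resseqs=np.array([1, 2, 3]), chains=["A"] * 3,
        coords=np.array([[4.0, 0, 0], [0, 4.0, 0], [0, 0, 4.0]]),
        is_water=np.zeros(3, bool), is_hetero=np.zeros(3, bool),
    )
    ref = ComplexStructure(protein=protein, ligand=mol)
    xyz = mol.coords()
    c, _, axes = np.linalg.svd(xyz - xyz.mean(axis=0), full_matrices=False)[0], None, None
    # rotate 60° about the ring normal
    ring = xyz[mol.is_heavy]
    centroid = ring.mean(axis=0)
    normal = np.cross(ring[1] - ring[0], ring[2] - ring[0])
    normal /= np.linalg.norm(normal)
    from ligplace._geometry import rotation_from_vector

    rot = rotation_from_vector(normal * np.pi / 3)
    moved_lig = mol.copy()
    moved_lig.set_coords((xyz - centroid) @ rot.T + centroid)
    model = ComplexStructure(protein=protein, ligand=moved_lig)
    assert lp.ligand_rmsd(model, ref) < 0.05
    assert lp.ligand_rmsd(model, ref, symmetry_corrected=False) > 1.0


def test_halogens_excluded_from_rmsd():
    """Displacing only a halogen leaves the halogen-free RMSD at ~0."""
    mol = lp.generate_conformers(lp.read_smiles("Clc1ccccc1"), max_confs=1, seed=2).molecule
    from ligplace.chem_io import ProteinStructure

    protein = ProteinStructure(
        elements=["C"] * 3, names=["CA", "CB", "CG"], resnames=["GLY"] * 3,
        resseqs=np.array([1, 2, 3]), chains=["A"] * 3,
        coords=np.array([[5.0, 0, 0], [0, 5.0, 0], [0, 0, 5.0]]),
        is_water=np.zeros(3, bool), is_hetero=np.zeros(3, bool),
    )
    ref = ComplexStructure(protein=protein, ligand=mol)
    moved = mol.copy()
    xyz = mol.coords().copy()
    cl = int(np.where(mol.is_halogen)[0][0])
    xyz[cl] += np.array([3.0, 0.0, 0.0])
    moved.set_coords(xyz)
    model = ComplexStructure(protein=protein, ligand=moved)
    assert lp.ligand_rmsd(model, ref) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_invariant_under_joint_rigid_motion(cheap_pocket):
    _, cx, _ = cheap_pocket
    jittered = cx.ligand.copy()
    rng = np.random.default_rng(8)
    jittered.set_coords(cx.ligand_coords() + rng.normal(scale=0.5, size=(cx.ligand.n_atoms, 3)))
    model = ComplexStructure(protein=cx.protein, ligand=jittered)
    base = lp.ligand_rmsd(model, cx)
    g = RigidTransform(random_rotation(rng), np.array([1.0, 2.0, 3.0]))
    moved_model = _moved_copy(model, g)
    moved_ref = _moved_copy(cx, g)
    assert lp.ligand_rmsd(moved_model, moved_ref) == pytest.approx(base, abs=1e-9)


def test_success_rates_printed_example_and_bounds():
    """17 of 24 targets with best-of-5 within 2.5 Å gives the 71% rate; the
    top-1 rate can never exceed the top-5 rate."""
    rmsds = {f"t{i}": [1.0, 3.0, 3.0, 3.0, 3.0] for i in range(17)}
    rmsds.update({f"t{i}": [9.0] * 5 for i in range(17, 24)})
    rate5 = lp.success_rates(rmsds, threshold=2.5, n=5)
    assert rate5 == pytest.approx(17 / 24)
    assert round(100 * rate5) == 71
    rng = np.random.default_rng(0)
    random_rmsds = {
        f"r{i}": list(rng.uniform(0.5, 6.0, size=5)) for i in range(30)
    }
    assert lp.success_rates(random_rmsds, n=1) <= lp.success_rates(random_rmsds, n=5)


def test_success_rate_all_failing_is_zero():
    assert lp.success_rates({"a": [5.0], "b": [7.0]}, threshold=2.5, n=1) == 0.0


def test_kendall_tau_known_values():
    assert lp.kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
    assert lp.kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
    # one discordant pair out of six: (5 - 1) / 6
    assert lp.kendall_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)


def test_kendall_tau_antisymmetric_and_errors():
    x = [1.0, 3.0, 2.0, 5.0, 4.0]
    y = [2.0, 1.0, 4.0, 3.0, 5.0]
    neg_y = [-v for v in y]
    assert lp.kendall_tau(x, y) == pytest.approx(-lp.kendall_tau(x, neg_y), abs=1e-12)
    with pytest.raises(InputError):
        lp.kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_matthews_cc_table():
    assert lp.matthews_cc(10, 0, 0, 10) == pytest.approx(1.0)
    assert lp.matthews_cc(5, 5, 5, 5) == 0.0
    tp, fp, fn, tn = 8, 2, 1, 9
    expected = (8 * 9 - 2 * 1) / np.sqrt((8 + 2) * (8 + 1) * (9 + 2) * (9 + 1))
    assert lp.matthews_cc(tp, fp, fn, tn) == pytest.approx(expected)
    assert lp.matthews_cc(3, 0, 0, 0) == 0.0  # degenerate table convention


def test_confusion_counts():
    truth = {"a": True, "b": False, "c": True, "d": False}
    pred = {"a": True, "b": True, "c": False, "d": False}
    assert confusion_counts(truth, pred) == (1, 1, 1, 1)
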