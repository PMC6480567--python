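"""Synthetic pocket fixtures: determinism, certification, perturbations."""

import numpy as np
import pytest

from irdl.dockcore import batch_field_score, build_grid, score_pose
from irdl.evaluation import hbond_set, rmsd
from irdl.structures import read_pdb
from irdl.synthetic import make_pocket_system, perturb_pose


def test_generation_is_deterministic():
    a = make_pocket_system("GAKDF", n_contacts=3, seed=9)
    b = make_pocket_system("GAKDF", n_contacts=3, seed=9)
    assert np.array_equal(a.planted_peptide.coords, b.planted_peptide.coords)
    assert np.array_equal(a.receptor.coords(), b.receptor.coords())
    assert a.design == b.design


def test_designed_hbond_count_is_exact(pocket):
    pairs = hbond_set(pocket.planted_peptide, pocket.receptor)
    assert len(pairs) == pocket.design["n_contacts"] == 3


def test_planted_pose_is_self_identical(pocket):
    ref = pocket.reference_system()
    assert rmsd(pocket.planted_peptide, ref, "whole") == 0.0


def test_certification_holds(pocket):
    """Planted pose beats >= 95% of fresh random in-box placements."""
    from scipy.spatial.transform import Rotation
    grid = build_grid(pocket.receptor, pocket.planted_peptide, spacing=0.5)
    planted = score_pose(grid, pocket.planted_peptide).total
    rng = np.random.default_rng(123)
    coords = pocket.planted_peptide.coords
    cen = coords.mean(axis=0)
    quats = rng.normal(size=(1000, 4))
    rots = Rotation.from_quat(quats / np.linalg.norm(quats, axis=1,
                                                     keepdims=True))
    trans = rng.uniform(grid.origin + 1, grid.box_max - 1, size=(1000, 3))
    batch = np.einsum("pij,aj->pai", rots.as_matrix(), coords - cen) \
        + trans[:, None, :]
    randoms = batch_field_score(grid, batch,
                                pocket.planted_peptide.topology)
    assert planted < np.percentile(randoms, 5.0)


def test_round_trip_through_pdb_preserves_metrics(pocket, tmp_path):
    paths = pocket.write(tmp_path)
    receptor = read_pdb(paths["receptor"], chain_policy="keep-all",
                        role="receptor")
    reference = read_pdb(paths["reference"], chain_policy="keep-all",
                         role="peptide")
    assert receptor.n_atoms == pocket.receptor.n_atoms
    from irdl.structures import assign_protonation
    receptor = assign_protonation(receptor)
    pairs = hbond_set(assign_protonation(reference), receptor)
    assert len(pairs) == pocket.design["n_contacts"]
    assert rmsd(assign_protonation(reference),
                pocket.reference_system()) <= 1e-3


def test_sequence_length_bounds():
    with pytest.raises(ValueError):
        make_pocket_system("AAA", seed=0)
    with pytest.raises(ValueError):
        make_pocket_system("A" * 11, seed=0)


def test_perturb_zero_is_identity(pocket):
    out = perturb_pose(pocket.planted_peptide, 0.0, seed=4)
    assert np.array_equal(out.coords, pocket.planted_peptide.coords)


def test_perturb_is_deterministic(pocket):
    a = perturb_pose(pocket.planted_peptide, 2.0, seed=5)
    b = perturb_pose(pocket.planted_peptide, 2.0, seed=5)
    assert np.array_equal(a.coords, b.coords)


def test_perturb_magnitude_calibration(pocket):
    ref = pocket.reference_system()
    draws = [rmsd(perturb_pose(pocket.planted_peptide, 3.0, seed=k), ref)
             for k in range(100)]
    assert 2.4 <= float(np.mean(draws)) <= 3.6
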