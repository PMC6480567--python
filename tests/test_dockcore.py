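"""Grid construction, surrogate scoring, and fragment docking."""

import numpy as np
import pytest

from irdl.conformers import enumerate_conformers
from irdl.dockcore import (BOUNDARY_PENALTY, Pose, ReceptorGrid,
                           SearchConfig, XP_WEIGHTS, build_grid,
                           dock_fragment, fragment_topology, rescore_xp,
                           score_in_place, score_pose)
from irdl.structures import (Atom, Chain, MolecularSystem, PeptideModel,
                             Residue, assign_protonation)


def _single_atom_receptor(charge=0.0):
    res = Residue(name="CAG", seq_index=1)
    res.atoms.append(Atom(name="CC", element="C", coords=[0.0, 0.0, 0.0],
                          partial_charge=charge))
    return MolecularSystem([Chain("R", [res])], role="receptor")


def test_grid_box_arithmetic():
    receptor = _single_atom_receptor()
    ref = np.array([[0.0, 0.0, 0.0], [10.0, 8.0, 6.0]])
    grid = build_grid(receptor, ref, spacing=0.5, margin=5.0)
    size = grid.box_max - grid.origin
    # bounding box 10x8x6 inflated by 5 on each side, up to one grid cell
    assert np.all(size >= np.array([20.0, 18.0, 16.0]) - 1e-9)
    assert np.all(size <= np.array([20.0, 18.0, 16.0]) + grid.spacing)


def test_zero_charge_receptor_has_zero_elec_field():
    grid = build_grid(_single_atom_receptor(0.0),
                      np.array([[0.0, 0.0, 0.0]]), spacing=0.6, margin=4.0)
    assert np.allclose(grid.fields["elec"], 0.0)


def test_steric_field_spherically_symmetric():
    grid = build_grid(_single_atom_receptor(),
                      np.array([[0.0, 0.0, 0.0]]), spacing=0.25, margin=5.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        r = rng.uniform(2.5, 4.0)
        pts = np.stack([d * r, -d * r])
        vals, inside = grid.interpolate("steric", pts)
        assert inside.all()
        assert vals[0] == pytest.approx(vals[1], abs=0.05)


def test_invalid_spacing_rejected():
    with pytest.raises(ValueError):
        build_grid(_single_atom_receptor(), np.zeros((1, 3)), spacing=0.0)


def test_score_pose_boundary_penalty(pocket, pocket_grid, seed_fragment):
    model, topo, planted = seed_fragment
    outside = planted + 200.0
    bd = score_pose(pocket_grid, Pose(topology=topo, coords=outside))
    n_heavy = int(topo.heavy.sum())
    assert bd.terms["vdw"] >= BOUNDARY_PENALTY * n_heavy
    inside = score_pose(pocket_grid, Pose(topology=topo, coords=planted))
    assert inside.total < bd.total


def test_planted_pose_counts_designed_hbonds(pocket, pocket_grid):
    bd = score_pose(pocket_grid, pocket.planted_peptide)
    assert bd.counts["n_hbonds"] == pocket.design["n_contacts"]


def test_score_total_is_sum_of_terms(pocket, pocket_grid, seed_fragment):
    _, topo, planted = seed_fragment
    bd = score_pose(pocket_grid, Pose(topology=topo, coords=planted))
    assert bd.total == pytest.approx(sum(bd.terms.values()))


def test_frame_invariance(pocket, seed_fragment):
    """Rigidly rotating receptor + cavity + pose leaves the score intact."""
    from scipy.spatial.transform import Rotation
    _, topo, planted = seed_fragment
    grid0 = build_grid(pocket.receptor, pocket.planted_peptide, spacing=0.4)
    s0 = score_pose(grid0, Pose(topology=topo, coords=planted)).total
    rot = Rotation.from_rotvec([0.3, -0.6, 0.2])
    receptor2 = pocket.receptor.copy()
    receptor2.set_coords(rot.apply(pocket.receptor.coords()))
    ref2 = pocket.planted_peptide.copy()
    ref2.coords = rot.apply(pocket.planted_peptide.coords)
    grid2 = build_grid(receptor2, ref2, spacing=0.4)
    s2 = score_pose(grid2, Pose(topology=topo,
                                coords=rot.apply(planted))).total
    assert s2 == pytest.approx(s0, abs=max(0.01 * abs(s0), 0.3))


def test_score_in_place_leaves_coords_and_is_idempotent(pocket_grid,
                                                        seed_fragment):
    _, topo, planted = seed_fragment
    pose = Pose(topology=topo, coords=planted.copy())
    before = pose.coords.copy()
    bd1 = score_in_place(pocket_grid, pose)
    assert np.array_equal(pose.coords, before)
    bd2 = score_in_place(pocket_grid, pose)
    assert bd1.terms == bd2.terms
    bd3 = score_pose(pocket_grid, pose)
    assert bd1.terms == bd3.terms


def test_rescore_xp_ranks_planted_over_perturbations(pocket, pocket_grid):
    from irdl.synthetic import perturb_pose
    planted = pocket.planted_peptide
    pool = [planted] + [perturb_pose(planted, 3.0 + 0.2 * k, seed=k)
                        for k in range(10)]
    totals = [rescore_xp(pocket_grid, p).total for p in pool]
    assert int(np.argmin(totals)) == 0
    assert sorted(np.argsort(totals)) == list(range(len(pool)))


def test_rescore_xp_zero_interaction_leaves_strain_only(seed_fragment):
    _, topo, planted = seed_fragment
    dims = (4, 4, 4)
    fields = {name: np.zeros(dims)
              for name in ("steric", "elec", "donor_aff", "acc_aff")}
    empty = ReceptorGrid(planted.min(axis=0) - 20.0, 20.0, fields,
                         np.zeros((0, 3)), np.zeros((0, 3)),
                         np.zeros((0, 3)), np.zeros((0, 3)))
    bd = rescore_xp(empty, Pose(topology=topo, coords=planted))
    nonstrain = {k: v for k, v in bd.terms.items()
                 if k != "internal_strain"}
    assert all(v == pytest.approx(0.0) for v in nonstrain.values())


def test_dock_fragment_contract(pocket, pocket_grid, seed_fragment):
    model, topo, planted = seed_fragment
    conf = enumerate_conformers(model, max_n=30, seed=5)
    cfg = SearchConfig(n_placements=200, n_targeted=100, top_refine=6,
                       refine_sweeps=6)
    poses = dock_fragment(pocket_grid, conf, n_poses=1, seed=5, config=cfg,
                          topology=topo)
    assert len(poses) == 1
    again = dock_fragment(pocket_grid, conf, n_poses=1, seed=5, config=cfg,
                          topology=topo)
    assert np.array_equal(poses[0].coords, again[0].coords)
    assert poses[0].score_total == again[0].score_total


def test_dock_fragment_recovers_planted(pocket, seed_fragment):
    """Recovery by construction: the planted seed fragment is found."""
    grid = build_grid(pocket.receptor, pocket.planted_peptide, spacing=0.4)
    model, topo, planted = seed_fragment
    conf = enumerate_conformers(model, max_n=120, seed=11)
    poses = dock_fragment(grid, conf, n_poses=24, seed=11, topology=topo)
    rmsds = [float(np.sqrt(((p.coords[topo.heavy]
                             - planted[topo.heavy]) ** 2)
                           .sum(axis=1).mean())) for p in poses]
    assert min(rmsds) <= 2.0


def test_grid_save_load_round_trip(pocket_grid, tmp_path):
    path = tmp_path / "grid.npz"
    pocket_grid.save(path)
    back = ReceptorGrid.load(path)
    assert np.allclose(back.origin, pocket_grid.origin)
    assert back.spacing == pocket_grid.spacing
    for name in pocket_grid.fields:
        assert np.allclose(back.fields[name], pocket_grid.fields[name])
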