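"""Covalent growth step: acid chloride, bond formation, topology, clusters."""

import networkx as nx
import numpy as np
import pytest

from irdl.conformers import enumerate_conformers
from irdl.dockcore import Pose, build_grid, fragment_topology
from irdl.geometry import dihedral
from irdl.linker import (AMIDE_BOND_LENGTH, GeometryError, LinkedPose,
                         MalformedTerminusError, check_topology,
                         cluster_poses, covalent_score, dock_covalent,
                         form_peptide_bond, linked_topology,
                         prepare_acid_chloride, relax_junction)
from irdl.structures import PeptideModel, build_peptide


def test_prepare_acid_chloride_substitution():
    frag = build_peptide("A")
    out = prepare_acid_chloride(frag)
    names = [a.name for a in out.atoms()]
    assert out.n_atoms == frag.n_atoms          # heavy count unchanged
    assert names.count("CL") == 1
    assert "OXT" not in names
    cl = next(a for a in out.atoms() if a.name == "CL")
    assert cl.element == "CL"


def test_prepare_acid_chloride_twice_fails():
    out = prepare_acid_chloride(build_peptide("AG"))
    with pytest.raises(MalformedTerminusError):
        prepare_acid_chloride(out)


def _linked_fixture(pocket):
    """A linked pose built from the planted sub-fragments of the pocket."""
    full = pocket.model
    px = pocket.planted_peptide.coords
    am = PeptideModel("DF")
    at = fragment_topology(am)
    anchor = Pose(topology=at, coords=np.array(
        [px[full.atom_index(3 + am.atom_res[k], am.atom_names[k])]
         for k in range(am.n_atoms)]), pose_id="anchor", res_offset=3)
    fm = PeptideModel("GAK")
    ft = fragment_topology(fm, acid_chloride=True)
    fx = np.array([px[full.atom_index(fm.atom_res[k], fm.atom_names[k])]
                   if fm.atom_names[k] != "OXT"
                   else px[full.atom_index(2, "C")] + np.array([1.7, 0, 0])
                   for k in range(fm.n_atoms)])
    frag = Pose(topology=ft, coords=fx, pose_id="frag", res_offset=0)
    return anchor, frag


def test_form_peptide_bond_geometry(pocket):
    anchor, frag = _linked_fixture(pocket)
    linked = form_peptide_bond(anchor, frag)
    assert abs(linked.junction_bond_length() - AMIDE_BOND_LENGTH) <= 0.05
    # trans-planar omega at the new bond
    m = linked.topology.model
    x = linked.coords
    omega = dihedral(x[m.atom_index(2, "CA")], x[m.atom_index(2, "C")],
                     x[m.atom_index(3, "N")], x[m.atom_index(3, "CA")])
    assert abs(abs(omega) - 180.0) <= 10.0
    # atom conservation: anchor + fragment - 1 (the leaving Cl)
    assert linked.topology.n_atoms == \
        anchor.topology.n_atoms + frag.topology.n_atoms - 1
    # planted sub-fragments are near-ideal: little movement beyond the Cl
    frag_names = {(fm_k, frag.topology.names[k])
                  for fm_k, k in zip(frag.topology.res_index,
                                     range(frag.topology.n_atoms))}
    assert linked.pose.parent_id == "anchor"


def test_form_peptide_bond_requires_acid_chloride(pocket):
    anchor, frag = _linked_fixture(pocket)
    plain = Pose(topology=anchor.topology, coords=anchor.coords)
    with pytest.raises(MalformedTerminusError):
        form_peptide_bond(anchor, plain)


def test_form_peptide_bond_rejects_distant_fragment(pocket):
    anchor, frag = _linked_fixture(pocket)
    far = frag.copy()
    far.coords = far.coords + 50.0
    with pytest.raises(GeometryError):
        form_peptide_bond(anchor, far)


def test_check_topology_accepts_correct_and_rejects_aberrant(pocket):
    anchor, frag = _linked_fixture(pocket)
    linked = form_peptide_bond(anchor, frag)
    assert check_topology(linked)
    # break the chain: drag the junction nitrogen far away
    bad = LinkedPose(pose=linked.pose.copy(), junction=linked.junction)
    bad.pose.coords[linked.junction[0]] += np.array([0.0, 0.0, 8.0])
    assert not check_topology(bad)


def test_check_topology_is_graph_not_label_based(pocket):
    anchor, frag = _linked_fixture(pocket)
    linked = form_peptide_bond(anchor, frag)
    # swapping two chemically equivalent carboxylate oxygens preserves the
    # perceived graph even though labels transpose
    m = linked.topology.model
    swapped = LinkedPose(pose=linked.pose.copy(), junction=linked.junction)
    i = m.atom_index(3, "OD1")
    j = m.atom_index(3, "OD2")
    swapped.pose.coords[[i, j]] = swapped.pose.coords[[j, i]]
    assert check_topology(swapped)


def test_relax_junction_freezes_distal_atoms(pocket, pocket_grid):
    anchor, frag = _linked_fixture(pocket)
    linked = form_peptide_bond(anchor, frag)
    from irdl.dockcore import score_pose
    before_score = score_pose(pocket_grid, linked.pose).total
    before = linked.coords.copy()
    out = relax_junction(linked, pocket_grid, sweeps=2)
    topo = linked.topology
    junction_res = {int(topo.res_index[linked.junction[0]]),
                    int(topo.res_index[linked.junction[1]])}
    for k in range(topo.n_atoms):
        if int(topo.res_index[k]) not in junction_res:
            assert np.array_equal(out.coords[k], before[k])
    assert score_pose(pocket_grid, out.pose).total <= before_score + 1e-9


def test_covalent_score_is_three_term_mean():
    lp = LinkedPose(pose=None, component_scores={
        "anchor": -6.0, "fragment": -4.0, "linked": -5.0})
    assert covalent_score(lp) == pytest.approx(-5.0)
    lp2 = LinkedPose(pose=None, component_scores={
        "anchor": -4.0, "fragment": -6.0, "linked": -5.0})
    assert covalent_score(lp2) == pytest.approx(covalent_score(lp))
    with pytest.raises(ValueError):
        covalent_score(LinkedPose(pose=None,
                                  component_scores={"anchor": -1.0}))


def _pose_cloud(pocket, n, spread=4.0):
    anchor, frag = _linked_fixture(pocket)
    base = form_peptide_bond(anchor, frag)
    rng = np.random.default_rng(3)
    out = []
    for k in range(n):
        lp = LinkedPose(pose=base.pose.copy(), junction=base.junction,
                        component_scores={"anchor": float(rng.normal()),
                                          "fragment": float(rng.normal()),
                                          "linked": float(rng.normal())})
        lp.pose.pose_id = f"cloud{k}"
        lp.pose.coords = lp.pose.coords + rng.normal(scale=spread, size=3)
        out.append(lp)
    return out


def test_cluster_poses_min_rule(pocket):
    few = _pose_cloud(pocket, 7)
    assert len(cluster_poses(few, k=15)) == 7


def test_cluster_poses_caps_at_k(pocket):
    many = _pose_cloud(pocket, 100)
    reps = cluster_poses(many, k=15)
    assert len(reps) == 15
    scores = [covalent_score(lp) for lp in reps]
    assert scores == sorted(scores)


def test_cluster_poses_collapses_duplicates(pocket):
    few = _pose_cloud(pocket, 4)
    twin = LinkedPose(pose=few[0].pose.copy(), junction=few[0].junction,
                      component_scores=dict(few[0].component_scores))
    twin.pose.pose_id = "twin"
    reps = cluster_poses(few + [twin], k=15)
    assert len(reps) == 4       # identical geometry never splits


def test_dock_covalent_links_and_conserves(pocket):
    grid = build_grid(pocket.receptor, pocket.planted_peptide, spacing=0.5)
    anchor, _ = _linked_fixture(pocket)
    fm = PeptideModel("GAK")
    ft = fragment_topology(fm, acid_chloride=True)
    mt = linked_topology("GAK", "DF")
    conf = enumerate_conformers(fm, max_n=24, seed=2)
    linked = dock_covalent(grid, anchor, conf, seed=2, fragment_topo=ft,
                           merged_topology=mt)
    assert linked
    for lp in linked:
        assert abs(lp.junction_bond_length() - AMIDE_BOND_LENGTH) <= 0.05
        assert lp.topology.n_atoms == \
            anchor.topology.n_atoms + ft.n_atoms - 1
        assert set(lp.component_scores) == {"anchor", "fragment", "linked"}
    again = dock_covalent(grid, anchor, conf, seed=2, fragment_topo=ft,
                          merged_topology=mt)
    assert len(again) == len(linked)
    for a, b in zip(linked, again):
        assert np.array_equal(a.coords, b.coords)
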