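"""Pose metrics: RMSD with symmetry matching, ranks, H-bond conservation."""

import itertools

import numpy as np
import pytest

from irdl import residues as rt
from irdl.dockcore import Pose, PoseTopology, fragment_topology
from irdl.evaluation import (AtomMatchError, hbond_conservation_ratio,
                             hbond_set, rank_first_correct, rmsd)
from irdl.structures import (Atom, Chain, MolecularSystem, PeptideModel,
                             Residue, assign_protonation, build_peptide)


def _pose(model, coords, offset=0):
    topo = fragment_topology(model)
    return Pose(topology=topo, coords=coords, res_offset=offset)


def brute_force_symmetry_rmsd(model, xa, xb, selection):
    """Enumerate every combination of symmetry swaps; return the minimum."""
    names = model.atom_names
    if selection == "backbone":
        idx = [k for k, n in enumerate(names) if n in rt.BACKBONE_NAMES]
        d = xa[idx] - xb[idx]
        return float(np.sqrt((d * d).sum(axis=1).mean()))
    swaps = []   # per-residue groups of jointly swapped index pairs
    for ri, resname in enumerate(model.seq3):
        for group in rt.SYMMETRY_GROUPS.get(resname, []):
            swaps.append([(model.atom_index(ri, a), model.atom_index(ri, b))
                          for a, b in group])
    best = None
    for combo in itertools.product([False, True], repeat=len(swaps)):
        ref = xb.copy()
        for apply_swap, group in zip(combo, swaps):
            if apply_swap:
                for i, j in group:
                    ref[[i, j]] = ref[[j, i]]
        d = xa - ref
        val = float(np.sqrt((d * d).sum(axis=1).mean()))
        best = val if best is None else min(best, val)
    return best


def test_rmsd_identity_and_translation():
    model = PeptideModel("GAF")
    x = model.coords()
    assert rmsd(_pose(model, x), _pose(model, x.copy())) == 0.0
    shifted = x + np.array([3.0, 0.0, 0.0])
    assert rmsd(_pose(model, shifted), _pose(model, x)) == \
        pytest.approx(3.0, abs=1e-12)
    assert rmsd(_pose(model, shifted), _pose(model, x), "backbone") == \
        pytest.approx(3.0, abs=1e-12)


def test_rmsd_matches_symmetry_enumeration_oracle():
    """Symmetry-aware RMSD equals brute force over all swap assignments."""
    model = PeptideModel("FDERY")   # aromatic rings + carboxylates + Arg
    rng = np.random.default_rng(9)
    base = model.coords()
    for trial in range(50):
        xa = base + rng.normal(scale=0.8, size=base.shape)
        xb = base + rng.normal(scale=0.8, size=base.shape)
        for sel in ("whole", "backbone"):
            expected = brute_force_symmetry_rmsd(model, xa, xb, sel)
            got = rmsd(_pose(model, xa), _pose(model, xb), sel)
            assert got == pytest.approx(expected, abs=1e-9)


def test_rmsd_is_pseudo_metric():
    model = PeptideModel("FDA")
    rng = np.random.default_rng(10)
    base = model.coords()
    for _ in range(10):
        xs = [base + rng.normal(scale=1.0, size=base.shape)
              for _ in range(3)]
        poses = [_pose(model, x) for x in xs]
        d01 = rmsd(poses[0], poses[1])
        d10 = rmsd(poses[1], poses[0])
        assert d01 == pytest.approx(d10, abs=1e-12)
        d02 = rmsd(poses[0], poses[2])
        d12 = rmsd(poses[1], poses[2])
        assert d02 <= d01 + d12 + 1e-9


def test_rmsd_errors_on_mismatched_sets():
    with pytest.raises(AtomMatchError):
        rmsd(_pose(PeptideModel("GA"), PeptideModel("GA").coords()),
             _pose(PeptideModel("GG"), PeptideModel("GG").coords()))


def test_rank_first_correct():
    model = PeptideModel("GAKDF")
    ref_x = model.coords()
    ref = _pose(model, ref_x)
    from irdl.synthetic import perturb_pose
    ladder = [perturb_pose(ref, m, seed=i)
              for i, m in enumerate([5.0, 4.0, 0.5, 0.2])]
    rank_bb, rank_wp = rank_first_correct(ladder, ref)
    assert rank_bb == 3
    assert rank_wp == 3
    # tightening thresholds never decreases a rank
    tight_bb, tight_wp = rank_first_correct(ladder, ref, 0.4, 0.4)
    assert tight_bb >= rank_bb and tight_wp >= rank_wp
    none_bb, none_wp = rank_first_correct(ladder[:2], ref)
    assert none_bb is None and none_wp is None


def _designed_complex(n_pairs, distance=2.9):
    """Peptide strand plus acceptor pseudo-atoms opposite backbone N."""
    model = PeptideModel("AAAAA")
    pep = assign_protonation(model.to_system(model.coords()))
    residues = []
    x = model.coords()
    for k in range(n_pairs):
        ni = model.atom_index(k, "N")
        cai = model.atom_index(k, "CA")
        # along the antecedent->donor axis: ideal (linear) donor angle
        prev_c = model.atom_index(k - 1, "C") if k > 0 else None
        ants = [cai] + ([prev_c] if prev_c is not None else [])
        direction = x[ni] - x[ants].mean(axis=0)
        direction /= np.linalg.norm(direction)
        pt = x[ni] + distance * direction
        res = Residue(name="HBA", seq_index=k + 1)
        res.atoms.append(Atom(name="OA", element="O", coords=pt))
        residues.append(res)
    receptor = MolecularSystem([Chain("R", residues)], role="receptor")
    return assign_protonation(pep), assign_protonation(receptor), model


def test_hbond_set_counts_designed_pairs():
    pep, receptor, model = _designed_complex(3)
    pairs = hbond_set(pep, receptor)
    assert len(pairs) == 3


def test_hbond_set_respects_distance_cutoff():
    pep, receptor, model = _designed_complex(2, distance=3.6)
    assert hbond_set(pep, receptor) == set()


def test_hbond_set_empty_for_apolar_receptor():
    pep = assign_protonation(build_peptide("AAA"))
    res = Residue(name="CAG", seq_index=1)
    res.atoms.append(Atom(name="CC", element="C", coords=[0.0, 0.0, 9.0]))
    receptor = MolecularSystem([Chain("R", [res])], role="receptor")
    assert hbond_set(pep, receptor) == set()


def test_hbond_conservation_ratio():
    pep, receptor, model = _designed_complex(4)
    assert hbond_conservation_ratio(pep, pep, receptor) == 1.0
    # shift one donor away: 3 of 4 reference bonds conserved -> 0.75
    moved = pep.copy()
    atoms = moved.atoms()
    ni = model.atom_index(3, "N")
    atoms[ni].coords = atoms[ni].coords + np.array([0.0, 0.0, 5.0])
    ratio = hbond_conservation_ratio(moved, pep, receptor)
    assert ratio == pytest.approx(0.75)
    # no reference bonds: defined as 1
    empty_rec = MolecularSystem(
        [Chain("R", [Residue(name="CAG", seq_index=1,
                             atoms=[Atom(name="CC", element="C",
                                         coords=[50.0, 50.0, 50.0])])])],
        role="receptor")
    assert hbond_conservation_ratio(moved, pep, empty_rec) == 1.0
    assert 0.0 <= ratio <= 1.0
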