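"""One growth step: covalent-constraint docking, amide formation, clustering.

The incoming fragment carries an acid-chloride C-terminus (Cl standing in
for the leaving group).  Placements are sampled with the carbonyl carbon
restrained near the anchored partial peptide's free N-terminal amine,
refined against the grid score plus anchor sterics under the restraint, and
fused by in-silico amide formation: the Cl leaves, a C-N bond is created at
the ideal amide length with a trans-planar omega, the junction is relaxed
locally, topology-checked, clustered, and scored with the covalent score
(mean of the two non-covalent component scores and the linked score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from . import residues as rt
from .conformers import ConformerSet, soft_lj
from .dockcore import (Pose, PoseTopology, ReceptorGrid, SearchConfig,
                       _PoseState, _refine_state, batch_field_score,
                       fragment_topology, score_arrays, score_in_place,
                       score_pose)
from .structures import MolecularSystem, PeptideModel

AMIDE_BOND_LENGTH = 1.33
AMIDE_BOND_TOL = 0.05
OMEGA_TOL = 10.0
# The carbonyl C may approach the anchor amine down to bond distance during
# covalent docking (placements are constructed at ideal amide geometry and
# sterics prevent collapse); only drifting too far is restrained.
RESTRAINT_WINDOW = (1.2, 4.0)   # A, carbonyl C to anchor N during docking
SAMPLE_AMINE_PSI = True         # enumerate the anchor's free-amine rotation


class MalformedTerminusError(ValueError):
    pass


class GeometryError(RuntimeError):
    pass


class NoLinkablePoseError(RuntimeError):
    pass


@dataclass
class LinkedPose:
    """A partial peptide extended by one fused fragment."""
    pose: Pose
    component_scores: dict[str, float] = field(default_factory=dict)
    junction: tuple[int, int] = (0, 0)   # (anchor N idx, fragment C idx)
    cluster_id: int | None = None

    @property
    def coords(self) -> np.ndarray:
        return self.pose.coords

    @property
    def topology(self) -> PoseTopology:
        return self.pose.topology

    def junction_bond_length(self) -> float:
        n_i, c_i = self.junction
        return float(np.linalg.norm(self.coords[n_i] - self.coords[c_i]))


def prepare_acid_chloride(fragment: MolecularSystem) -> MolecularSystem:
    """Replace the free C-terminal carboxyl O(H) by Cl (leaving group).

    Heavy-atom count is unchanged; the Cl inherits the terminal-oxygen
    position extended to the ideal C-Cl bond length.
    """
    out = fragment.copy()
    last = None
    for res in out.residues():
        if res.name in rt.STANDARD_RESIDUES:
            last = res
    if last is None or not last.has_atom("OXT") or not last.has_atom("C"):
        raise MalformedTerminusError(
            "fragment has no free C-terminal carboxyl")
    oxt = last.atom("OXT")
    c = last.atom("C")
    direction = oxt.coords - c.coords
    direction = direction / np.linalg.norm(direction)
    oxt.name = "CL"
    oxt.element = "CL"
    oxt.coords = c.coords + 1.79 * direction
    oxt.is_backbone = False
    return out


def merge_model(fragment_seq: str, anchor_seq: str) -> PeptideModel:
    """Topology of the grown chain (fragment is the N-terminal part)."""
    return PeptideModel(fragment_seq + anchor_seq)


def form_peptide_bond(anchor: Pose, placed_fragment: Pose,
                      merged_topology: PoseTopology | None = None
                      ) -> LinkedPose:
    """Fuse an acid-chloride fragment onto the anchor's N-terminal amine.

    The Cl is removed, the fragment is rigidly shifted so the new C-N bond
    has the ideal amide length, and rotated about the new bond to a
    trans-planar omega.  Atom ordering of the merged pose follows the
    combined-sequence peptide topology (N- to C-terminal).
    """
    frag_topo = placed_fragment.topology
    anch_topo = anchor.topology
    if frag_topo.leaving_group is None:
        raise MalformedTerminusError("fragment carries no acid-chloride "
                                     "terminus")
    fx = placed_fragment.coords.copy()
    ax = anchor.coords
    nf = len(frag_topo.model.seq3)
    c_i = frag_topo.model.atom_index(nf - 1, "C")
    ca_f = frag_topo.model.atom_index(nf - 1, "CA")
    n_a = _atom_in_residue(anch_topo, 0, "N")
    ca_a = _atom_in_residue(anch_topo, 0, "CA")

    d0 = float(np.linalg.norm(fx[c_i] - ax[n_a]))
    if not (1.0 <= d0 <= 4.5):
        raise GeometryError(f"junction distance {d0:.2f} A outside linkable "
                            "range")
    o_f = frag_topo.model.atom_index(nf - 1, "O")
    c_a = _atom_in_residue(anch_topo, 0, "C")
    fx = _snap_to_junction(fx, (ca_f, c_i, o_f), ax, (n_a, ca_a, c_a),
                           anchor_heavy=ax[anch_topo.heavy])

    frag_seq = frag_topo.sequence
    anch_seq = anch_topo.sequence
    topo = merged_topology or linked_topology(frag_seq, anch_seq)
    merged = np.zeros((topo.n_atoms, 3))
    m_model = topo.model
    for k in range(topo.n_atoms):
        ri = int(topo.res_index[k])
        name = topo.names[k]
        if ri < nf:
            merged[k] = fx[frag_topo.model.atom_index(ri, name)]
        else:
            merged[k] = ax[_atom_in_residue(anch_topo, ri - nf, name)]
    junction = (m_model.atom_index(nf, "N"), m_model.atom_index(nf - 1, "C"))
    pose = Pose(topology=topo, coords=merged,
                step_index=anchor.step_index + 1,
                parent_id=anchor.pose_id,
                pose_id=f"{anchor.pose_id}+{placed_fragment.pose_id}",
                res_offset=placed_fragment.res_offset)
    linked = LinkedPose(pose=pose, junction=junction)
    blen = linked.junction_bond_length()
    if abs(blen - AMIDE_BOND_LENGTH) > AMIDE_BOND_TOL:
        raise GeometryError(f"junction bond length {blen:.3f} A out of "
                            "tolerance")
    return linked


def _snap_to_junction(fx: np.ndarray, frag_refs, ax: np.ndarray,
                      anchor_refs, anchor_heavy: np.ndarray) -> np.ndarray:
    """Rigidly map the fragment's carbonyl triad onto an ideal amide frame.

    The ideal carbonyl carbon sits at the amide bond length from the anchor
    amine with the ideal angle at N and a trans-planar omega; the remaining
    freedom (the anchor residue's phi) is scanned and the least disruptive,
    least clashing solution kept, so bond length, junction angles and omega
    are exact by construction while the fragment's internal geometry is
    untouched.
    """
    from .geometry import place_atom
    from scipy.spatial.transform import Rotation as _R

    ca_f, c_i, o_f = frag_refs
    n_a, ca_a, c_a = anchor_refs
    triad = np.stack([fx[ca_f], fx[c_i], fx[o_f]])
    best = None
    for phi in np.arange(-180.0, 180.0, 10.0):
        c_star = place_atom(ax[c_a], ax[ca_a], ax[n_a],
                            AMIDE_BOND_LENGTH, 121.7, phi)
        ca_star = place_atom(ax[ca_a], ax[n_a], c_star, 1.525, 116.2, 180.0)
        o_star = place_atom(ax[ca_a], ax[n_a], c_star, 1.231, 123.0, 0.0)
        target = np.stack([ca_star, c_star, o_star])
        t_cen = target.mean(axis=0)
        f_cen = triad.mean(axis=0)
        rot, _ = _R.align_vectors(target - t_cen, triad - f_cen)
        moved = rot.apply(fx - f_cen) + t_cen
        disp = float(((moved - fx) ** 2).sum(axis=1).mean())
        d = np.linalg.norm(moved[:, None, :] - anchor_heavy[None, :, :],
                           axis=2)
        d[c_i, :] = np.inf   # the new bond partner is allowed to be close
        clashes = int((d < 2.2).sum())
        cost = disp + 25.0 * clashes
        if best is None or cost < best[0]:
            best = (cost, moved)
    return best[1]


def linked_topology(fragment_seq: str, anchor_seq: str,
                    pH: float = 7.4) -> PoseTopology:
    return fragment_topology(merge_model(fragment_seq, anchor_seq), pH=pH)


def _atom_in_residue(topo: PoseTopology, res_index: int, name: str) -> int:
    if topo.model is not None:
        return topo.model.atom_index(res_index, name)
    for k in range(topo.n_atoms):
        if topo.res_index[k] == res_index and topo.names[k] == name:
            return k
    raise KeyError((res_index, name))


def relax_junction(linked: LinkedPose, grid: ReceptorGrid,
                   sweeps: int = 2, step: float = 0.1) -> LinkedPose:
    """Cartesian relaxation of the two residues flanking the new bond.

    Only atoms of those two residues move; a move is accepted when it
    strictly lowers the pose score while keeping every touched bond within
    0.12 A of its pre-relaxation length (the receptor and all other peptide
    atoms stay fixed), so the final score never exceeds the input score.
    """
    topo = linked.topology
    model = topo.model
    nf_res = topo.res_index[linked.junction[1]]
    na_res = topo.res_index[linked.junction[0]]
    movable = np.where(np.isin(topo.res_index, [nf_res, na_res]))[0]
    bonds = list(model.bonds) + [tuple(linked.junction)]
    ref_len = {b: float(np.linalg.norm(linked.coords[b[0]]
                                       - linked.coords[b[1]]))
               for b in bonds}
    # the new amide bond itself stays within its formation tolerance
    ref_len[tuple(linked.junction)] = AMIDE_BOND_LENGTH
    coords = linked.coords.copy()
    pose = linked.pose.copy()
    pose.coords = coords
    best = score_pose(grid, pose).total
    moves = step * np.vstack([np.eye(3), -np.eye(3)])
    for _ in range(max(sweeps, 0)):
        improved = False
        for a in movable:
            touched = [b for b in bonds if a in b]
            for mv in moves:
                trial = coords[a] + mv
                ok = all(abs(np.linalg.norm(
                    (trial if b[0] == a else coords[b[0]])
                    - (trial if b[1] == a else coords[b[1]])) - ref_len[b])
                    <= (AMIDE_BOND_TOL if b == tuple(linked.junction)
                        else 0.12) for b in touched)
                if not ok:
                    continue
                old = coords[a].copy()
                coords[a] = trial
                val = score_pose(grid, pose).total
                if val < best - 1e-9:
                    best = val
                    improved = True
                else:
                    coords[a] = old
        if not improved:
            break
    out_pose = linked.pose.copy()
    out_pose.coords = coords
    bd = score_pose(grid, out_pose)
    out_pose.score_total = bd.total
    out_pose.score_terms = dict(bd.terms)
    return LinkedPose(pose=out_pose,
                      component_scores=dict(linked.component_scores),
                      junction=linked.junction,
                      cluster_id=linked.cluster_id)


# ---------------------------------------------------------------------------
# topology conservation
# ---------------------------------------------------------------------------

def relax_linked(linked: LinkedPose, grid: ReceptorGrid,
                 sweeps: int = 6) -> LinkedPose:
    """Whole-peptide relaxation of a linked pose against the rigid receptor.

    The merged pose is re-expressed in torsion space (all bonded geometry
    ideal, junction included) and descended over rigid-body and torsion
    coordinates against the pose score — the peptide is fully flexible, the
    receptor fixed.  Used on cluster representatives to let the grown chain
    settle into the cavity.
    """
    from .dockcore import SearchConfig, state_from_coords

    topo = linked.topology
    state = state_from_coords(topo.model, linked.coords)
    fine = SearchConfig(refine_sweeps=sweeps, trans_step=0.4,
                        rot_step=10.0, tor_step=10.0)

    def objective(xyz):
        return score_arrays(grid, xyz, topo).total

    best, best_val = _refine_state(state, objective, fine)

    # backbone rotamer-hop pass: a residue trapped one (phi, psi) rotamer
    # away cannot be fixed by small-step descent; each hop is applied in
    # torsion space and the whole pose rigidly re-fitted onto its previous
    # coordinates so the anchored parts stay put, accepted only when the
    # score improves
    from .conformers import BACKBONE_ROTAMERS
    model = topo.model
    tor_by_res: dict[int, dict[str, int]] = {}
    for k, t in enumerate(model.torsions):
        if t.name in ("phi", "psi"):
            tor_by_res.setdefault(t.res_index, {})[t.name] = k
    for _ in range(2):
        improved = False
        for ri, slots in sorted(tor_by_res.items()):
            for phi_v, psi_v in BACKBONE_ROTAMERS:
                tor = np.array(best.torsions, dtype=float, copy=True)
                if "phi" in slots:
                    tor[slots["phi"]] = phi_v
                if "psi" in slots:
                    tor[slots["psi"]] = psi_v
                prev = best.coords()
                gen = model.coords(tor)
                gc, pc = gen.mean(axis=0), prev.mean(axis=0)
                rot, _ = Rotation.align_vectors(prev - pc, gen - gc)
                cand = _PoseState(model, tor, rot, pc - rot.apply(gc))
                val = objective(cand.coords())
                if val < best_val - 1e-9:
                    best, best_val, improved = cand, val, True
        if not improved:
            break
    best, best_val = _refine_state(best, objective, fine)

    # sidechain rotamer pass: chi torsions can be trapped a full rotamer
    # away, which small-step descent cannot fix
    chi_idx = [k for k, t in enumerate(topo.model.torsions)
               if t.name.startswith("chi")]
    for _ in range(2):
        improved = False
        for k in chi_idx:
            current = best.torsions[k]
            for rot in (current + 120.0, current - 120.0):
                cand = best.copy()
                cand.set_torsion(k, rot)
                val = objective(cand.coords())
                if val < best_val - 1e-9:
                    best, best_val, improved = cand, val, True
        if not improved:
            break
    best, _ = _refine_state(best, objective, fine)
    pose = linked.pose.copy()
    pose.coords = best.coords()
    bd = score_arrays(grid, pose.coords, topo)
    pose.score_total = bd.total
    pose.score_terms = dict(bd.terms)
    return LinkedPose(pose=pose,
                      component_scores=dict(linked.component_scores),
                      junction=linked.junction,
                      cluster_id=linked.cluster_id)


def perceive_bonds(coords: np.ndarray, elements: list[str]) -> nx.Graph:
    """Distance-based bond perception: covalent-radius sum scaled by 1.25."""
    g = nx.Graph()
    n = len(coords)
    g.add_nodes_from((i, {"element": elements[i]}) for i in range(n))
    radii = np.array([rt.COVALENT_RADII.get(e, 0.77) for e in elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    cut = 1.25 * (radii[:, None] + radii[None, :])
    ii, jj = np.where((d <= cut) & (d > 0.4))
    g.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)
    return g


def check_topology(linked: LinkedPose,
                   expected: nx.Graph | None = None) -> bool:
    """True iff the distance-perceived bond graph matches the expected one.

    Comparison is element-coloured graph isomorphism, so atom transpositions
    that preserve connectivity pass while aberrant bonds (e.g. to a
    sidechain oxygen) fail.
    """
    topo = linked.topology
    if expected is None:
        expected = topo.model.bond_graph()
        nx.set_node_attributes(
            expected, {i: e for i, e in enumerate(topo.elements)}, "element")
    perceived = perceive_bonds(linked.coords, topo.elements)
    if perceived.number_of_edges() != expected.number_of_edges():
        return False
    return nx.is_isomorphic(
        perceived, expected,
        node_match=lambda a, b: a.get("element") == b.get("element"))


# ---------------------------------------------------------------------------
# clustering and covalent scoring
# ---------------------------------------------------------------------------

def covalent_score(linked: LinkedPose) -> float:
    """Mean of (anchor noncovalent, fragment noncovalent, linked covalent)."""
    required = ("anchor", "fragment", "linked")
    missing = [k for k in required if k not in linked.component_scores]
    if missing:
        raise ValueError(f"missing component scores: {missing}")
    return float(np.mean([linked.component_scores[k] for k in required]))


def cluster_poses(poses: list[LinkedPose], k: int = 15) -> list[LinkedPose]:
    """Average-linkage clustering on pairwise heavy-atom RMSD.

    Returns one representative per cluster (the best covalent score),
    ranked by covalent score; at most ``min(k, n)`` representatives, fewer
    when geometries coincide.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    n = len(poses)
    if n == 1:
        poses[0].cluster_id = 0
        return list(poses)
    heavy = poses[0].topology.heavy
    X = np.stack([p.coords[heavy] for p in poses])
    diff = X[:, None, :, :] - X[None, :, :, :]
    rmsd_mat = np.sqrt((diff ** 2).sum(axis=3).mean(axis=2))
    condensed = squareform(rmsd_mat, checks=False)
    z = linkage(condensed, method="average")
    # identical geometries always share a cluster, even when k >= n
    n_distinct = len(set(fcluster(z, t=1e-9, criterion="distance")))
    labels = fcluster(z, t=min(k, n_distinct), criterion="maxclust")
    reps: list[LinkedPose] = []
    for c in sorted(set(labels)):
        members = [p for p, lab in zip(poses, labels) if lab == c]
        best = min(members, key=lambda p: (covalent_score(p), p.pose.pose_id))
        best.cluster_id = int(c)
        reps.append(best)
    reps.sort(key=lambda p: (covalent_score(p), p.pose.pose_id))
    return reps


# ---------------------------------------------------------------------------
# covalent-constraint docking
# ---------------------------------------------------------------------------

def dock_covalent(grid: ReceptorGrid, anchor: Pose,
                  fragment: ConformerSet, seed: int = 0,
                  config: SearchConfig | None = None,
                  fragment_topo: PoseTopology | None = None,
                  merged_topology: PoseTopology | None = None,
                  n_poses: int = 8,
                  relax_sweeps: int = 1) -> list[LinkedPose]:
    """Dock a fragment under the junction proximity restraint and link it.

    For every conformer, placements are enumerated at ideal junction
    geometry over the anchor residue's phi and free-amine orientation,
    scored against the grid plus anchor sterics, refined under the
    proximity restraint (the carbonyl carbon may approach the amine down to
    bond distance; drifting beyond 4.0 A is penalised), and fused.  All anchor atoms stay fixed during docking; the
    junction relaxation afterwards may move only the two flanking residues.
    """
    config = config or SearchConfig(n_placements=250, top_refine=6,
                                    refine_sweeps=10)
    f_topo = fragment_topo or fragment_topology(fragment.model,
                                                acid_chloride=True)
    if f_topo.leaving_group is None:
        raise MalformedTerminusError("fragment topology lacks the "
                                     "acid-chloride terminus")
    rng = np.random.default_rng(seed)
    nf = len(fragment.model.seq3)
    c_i = fragment.model.atom_index(nf - 1, "C")
    ca_f = fragment.model.atom_index(nf - 1, "CA")
    o_f = fragment.model.atom_index(nf - 1, "O")
    n_a = _atom_in_residue(anchor.topology, 0, "N")
    ca_a = _atom_in_residue(anchor.topology, 0, "CA")
    c_a = _atom_in_residue(anchor.topology, 0, "C")
    ax = anchor.coords
    n_xyz = ax[n_a]
    heavy_mask = anchor.topology.heavy.copy()
    heavy_mask[n_a] = False    # the amine may be repositioned per candidate
    anchor_heavy = ax[heavy_mask]

    lo_r, hi_r = RESTRAINT_WINDOW
    # ideal-junction construction: with the anchor fixed and the junction
    # geometry ideal, the fragment placement is determined by the anchor
    # residue's phi AND by the orientation of its free amine (the anchor's
    # first-residue psi, which nothing constrained during earlier steps);
    # both are enumerated, and the amine is repositioned accordingly when
    # the bond is formed (the junction residues may be re-optimised).
    from .geometry import place_atom
    n_next = _atom_in_residue(anchor.topology, 1, "N") \
        if len(anchor.topology.model.seq3) > 1 else None
    psi_grid = [None]   # None = keep the anchor's amine where it is
    if n_next is not None and SAMPLE_AMINE_PSI:
        psi_grid = [None] + [float(p + rng.uniform(-8.0, 8.0))
                             for p in np.arange(-180.0, 180.0, 72.0)]
    triads = []   # (target triad, n_star)
    for psi in psi_grid:
        if psi is None:
            n_star = n_xyz
        else:
            n_star = place_atom(ax[n_next], ax[c_a], ax[ca_a],
                                1.458, 111.2, psi)
        for phi in np.arange(-180.0, 180.0, 30.0):
            p = phi + float(rng.uniform(-4.0, 4.0))
            c_star = place_atom(ax[c_a], ax[ca_a], n_star,
                                AMIDE_BOND_LENGTH, 121.7, p)
            ca_star = place_atom(ax[ca_a], n_star, c_star, 1.525, 116.2,
                                 180.0)
            o_star = place_atom(ax[ca_a], n_star, c_star, 1.231, 123.0, 0.0)
            triads.append((np.stack([ca_star, c_star, o_star]), n_star))

    candidates = []
    order = 0
    for ci, conf in enumerate(fragment):
        triad_f = np.stack([conf.coords[ca_f], conf.coords[c_i],
                            conf.coords[o_f]])
        f_cen = triad_f.mean(axis=0)
        rot_list, trans_list = [], []
        for target, _n_star in triads:
            t_cen = target.mean(axis=0)
            rot, _ = Rotation.align_vectors(target - t_cen, triad_f - f_cen)
            rot_list.append(rot)
            trans_list.append(t_cen - rot.apply(f_cen))
        mats = np.stack([r.as_matrix() for r in rot_list])
        trans = np.stack(trans_list)
        batch = np.einsum("pij,aj->pai", mats, conf.coords) \
            + trans[:, None, :]
        cheap = batch_field_score(grid, batch, f_topo)
        cheap += _anchor_steric_batch(batch, f_topo, anchor_heavy)
        top = np.argsort(cheap, kind="stable")[:3]
        for p in top:
            state = _PoseState(fragment.model, conf.torsions.copy(),
                               rot_list[int(p)], trans[p])
            centroid = batch[p].mean(axis=0)
            candidates.append((float(cheap[p]), order, state, centroid,
                               triads[int(p)][1]))
            order += 1
    candidates.sort(key=lambda c: (c[0], c[1]))
    from .dockcore import _select_diverse
    candidates = _select_diverse(candidates, config.top_refine,
                                 min_separation=1.2)

    def _restraint(xyz, n_ref):
        d = float(np.linalg.norm(xyz[c_i] - n_ref))
        if d > hi_r:
            return 50.0 * (d - hi_r) ** 2
        if d < lo_r:
            return 50.0 * (lo_r - d) ** 2
        return 0.0

    def objective(xyz, n_ref):
        val = float(batch_field_score(grid, xyz[None], f_topo)[0])
        val += float(_anchor_steric_batch(xyz[None], f_topo, anchor_heavy)[0])
        return val + _restraint(xyz, n_ref)

    def exact_objective(xyz, n_ref):
        val = score_arrays(grid, xyz, f_topo).total
        val += float(_anchor_steric_batch(xyz[None], f_topo, anchor_heavy)[0])
        return val + _restraint(xyz, n_ref)

    anchor_score = None
    out: list[LinkedPose] = []
    for rank, (_, idx, state, _cen, n_star) in enumerate(candidates):
        best, _ = _refine_state(
            state, lambda xyz: objective(xyz, n_star), config)
        best, _ = _refine_state(
            best, lambda xyz: exact_objective(xyz, n_star), config.polish())
        xyz = best.coords()
        d = float(np.linalg.norm(xyz[c_i] - n_star))
        if not (lo_r <= d <= hi_r):
            continue
        frag_pose = Pose(topology=f_topo, coords=xyz,
                         pose_id=f"c{seed}.{rank}",
                         res_offset=anchor.res_offset - nf)
        anchor_used = anchor
        if not np.array_equal(n_star, n_xyz):
            anchor_used = anchor.copy()
            anchor_used.coords[n_a] = n_star
        try:
            linked = form_peptide_bond(anchor_used, frag_pose,
                                       merged_topology)
        except GeometryError:
            continue
        linked = relax_junction(linked, grid, sweeps=relax_sweeps)
        if anchor_score is None:
            anchor_score = score_in_place(grid, anchor).total
        linked.component_scores = {
            "anchor": anchor_score,
            "fragment": score_in_place(grid, frag_pose).total,
            "linked": score_in_place(grid, linked.pose).total,
        }
        out.append(linked)
    if not out:
        raise NoLinkablePoseError(
            f"no placement satisfied the junction restraint for anchor "
            f"{anchor.pose_id!r}")
    return out[:n_poses]


def _anchor_steric_batch(batch: np.ndarray, topo: PoseTopology,
                         anchor_heavy: np.ndarray) -> np.ndarray:
    """Soft-LJ interaction of fragment heavy atoms with the fixed anchor."""
    fh = batch[:, topo.heavy, :]
    d = np.linalg.norm(fh[:, :, None, :] - anchor_heavy[None, None, :, :],
                       axis=3)
    return soft_lj(d).sum(axis=(1, 2))
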