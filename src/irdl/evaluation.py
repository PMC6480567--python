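"""Pose-quality metrics: RMSD, rank of first correct pose, H-bond conservation.

RMSD follows the docking convention: heavy atoms only, computed in the fixed
receptor frame *without* superposition, with chemically equivalent sidechain
atoms (aromatic ring flips, carboxylate and guanidinium oxygens/nitrogens)
matched so as to minimise the deviation.  A pose is a correct docking
solution when its backbone RMSD is below 2 A or its whole-peptide RMSD is
below 3 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import residues as rt
from .dockcore import Pose
from .structures import (MolecularSystem, hbond_acceptors, hbond_donors)

BACKBONE_RMSD_THRESHOLD = 2.0
WHOLE_RMSD_THRESHOLD = 3.0
HBOND_DISTANCE_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 120.0


class AtomMatchError(ValueError):
    def __init__(self, unmatched):
        self.unmatched = unmatched
        super().__init__(f"unmatched atoms between pose and reference: "
                         f"{sorted(unmatched)[:10]}"
                         f"{'...' if len(unmatched) > 10 else ''}")


@dataclass
class EvaluationReport:
    backbone_rmsd: list[float]
    whole_rmsd: list[float]
    rank_first_correct_bb: int | None
    rank_first_correct_wp: int | None
    hbond_ratio: float | None = None

    def to_rows(self):
        return [{"rank": i + 1, "rmsd_bb": bb, "rmsd_wp": wp}
                for i, (bb, wp) in enumerate(zip(self.backbone_rmsd,
                                                 self.whole_rmsd))]


def _atom_table(obj):
    """-> dict (res_key, atom_name) -> xyz for heavy atoms, plus resname map.

    ``res_key`` is the 0-based position among standard residues so that a
    pose and a reference numbered differently still align by sequence
    position.
    """
    table = {}
    resnames = {}
    if isinstance(obj, Pose):
        topo = obj.topology
        for k in range(topo.n_atoms):
            if not topo.heavy[k]:
                continue
            ri = int(topo.res_index[k]) + obj.res_offset
            table[(ri, topo.names[k])] = obj.coords[k]
            resnames[ri] = topo.resnames[int(topo.res_index[k])]
    elif isinstance(obj, MolecularSystem):
        ri = 0
        for res in obj.residues():
            if res.name not in rt.STANDARD_RESIDUES:
                continue
            for a in res.atoms:
                if not a.is_hydrogen:
                    table[(ri, a.name)] = a.coords
            resnames[ri] = res.name
            ri += 1
    else:
        raise TypeError(f"cannot evaluate object of type {type(obj)!r}")
    return table, resnames


def rmsd(pose, reference, selection: str = "whole") -> float:
    """Heavy-atom RMSD in the shared receptor frame (no superposition).

    ``selection`` is ``backbone`` ({N, CA, C, O}) or ``whole``.  Symmetry-
    equivalent sidechain atoms are matched to minimise the result; the
    groups are independent per residue, so each is resolved separately.
    """
    if selection not in ("backbone", "whole"):
        raise ValueError(f"unknown selection {selection!r}")
    pt, presn = _atom_table(pose)
    rtab, rresn = _atom_table(reference)
    # a partial (still-growing) pose is compared against the corresponding
    # residues of the full reference
    pose_res = {k[0] for k in pt}
    rtab = {k: v for k, v in rtab.items() if k[0] in pose_res}
    if selection == "backbone":
        pt = {k: v for k, v in pt.items() if k[1] in rt.BACKBONE_NAMES}
        rtab = {k: v for k, v in rtab.items() if k[1] in rt.BACKBONE_NAMES}
    common = set(pt) & set(rtab)
    unmatched = (set(pt) ^ set(rtab))
    if unmatched:
        raise AtomMatchError(unmatched)
    if not common:
        raise AtomMatchError({"<empty selection>"})

    total_ss = 0.0
    n = 0
    by_res: dict[int, list] = {}
    for key in common:
        by_res.setdefault(key[0], []).append(key)
    for ri, keys in by_res.items():
        resname = rresn.get(ri, "")
        groups = rt.SYMMETRY_GROUPS.get(resname, []) if \
            selection == "whole" else []
        grouped = {name for g in groups for pair in g for name in pair}
        for key in keys:
            if key[1] in grouped:
                continue
            d = pt[key] - rtab[key]
            total_ss += float(d @ d)
            n += 1
        for g in groups:
            present = [(a, b) for a, b in g
                       if (ri, a) in common and (ri, b) in common]
            if not present:
                continue
            ss_id = sum(float((pt[(ri, a)] - rtab[(ri, a)])
                              @ (pt[(ri, a)] - rtab[(ri, a)]))
                        + float((pt[(ri, b)] - rtab[(ri, b)])
                                @ (pt[(ri, b)] - rtab[(ri, b)]))
                        for a, b in present)
            ss_sw = sum(float((pt[(ri, a)] - rtab[(ri, b)])
                              @ (pt[(ri, a)] - rtab[(ri, b)]))
                        + float((pt[(ri, b)] - rtab[(ri, a)])
                                @ (pt[(ri, b)] - rtab[(ri, a)]))
                        for a, b in present)
            total_ss += min(ss_id, ss_sw)
            n += 2 * len(present)
    return float(np.sqrt(total_ss / n))


def rank_first_correct(ranked_poses, reference,
                       bb_threshold: float = BACKBONE_RMSD_THRESHOLD,
                       wp_threshold: float = WHOLE_RMSD_THRESHOLD):
    """1-based rank of the first pose under each RMSD threshold (or None)."""
    if not ranked_poses:
        raise ValueError("empty pose list")
    rank_bb = rank_wp = None
    for i, pose in enumerate(ranked_poses, start=1):
        if rank_bb is None and rmsd(pose, reference,
                                    "backbone") < bb_threshold:
            rank_bb = i
        if rank_wp is None and rmsd(pose, reference,
                                    "whole") < wp_threshold:
            rank_wp = i
        if rank_bb is not None and rank_wp is not None:
            break
    return rank_bb, rank_wp


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _angle(a, b, c) -> float:
    v, w = a - b, c - b
    cosang = float(v @ w / (np.linalg.norm(v) * np.linalg.norm(w) + 1e-12))
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def hbond_set(peptide_pose, receptor: MolecularSystem,
              distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
              angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> set:
    """Peptide-receptor hydrogen-bond pairs by geometric criteria.

    A pair qualifies when the heavy-atom donor-acceptor distance is at most
    3.5 A and the donor angle (antecedent-donor-acceptor, the most
    favourable antecedent) is at least 120 degrees.  Pairs are identified by
    ((peptide residue, atom name), (receptor chain, residue, atom name)).
    """
    pep_sys = _as_system(peptide_pose)
    rec_atoms = receptor.atoms()
    rec_xyz = np.array([a.coords for a in rec_atoms])
    rec_labels = receptor.atom_labels()
    pep_atoms = pep_sys.atoms()
    pep_xyz = np.array([a.coords for a in pep_atoms])
    pep_labels = [(r.seq_index, a.name) for r in pep_sys.residues()
                  for a in r.atoms]

    pairs = set()
    rec_donors = hbond_donors(receptor)
    rec_acc = hbond_acceptors(receptor)
    pep_donors = hbond_donors(pep_sys)
    pep_acc = hbond_acceptors(pep_sys)

    for di, ants in pep_donors:
        for aj in rec_acc:
            d = float(np.linalg.norm(pep_xyz[di] - rec_xyz[aj]))
            if d > distance_cutoff:
                continue
            angs = [_angle(pep_xyz[k], pep_xyz[di], rec_xyz[aj])
                    for k in ants] or [180.0]
            if max(angs) >= angle_cutoff:
                pairs.add((pep_labels[di], rec_labels[aj]))
    for ai in pep_acc:
        for dj, ants in rec_donors:
            d = float(np.linalg.norm(pep_xyz[ai] - rec_xyz[dj]))
            if d > distance_cutoff:
                continue
            angs = [_angle(rec_xyz[k], rec_xyz[dj], pep_xyz[ai])
                    for k in ants] or [180.0]
            if max(angs) >= angle_cutoff:
                pairs.add((pep_labels[ai], rec_labels[dj]))
    return pairs


def _as_system(peptide_pose) -> MolecularSystem:
    if isinstance(peptide_pose, MolecularSystem):
        return peptide_pose
    if isinstance(peptide_pose, Pose):
        from .structures import assign_protonation
        sys_ = peptide_pose.topology.to_system(peptide_pose.coords)
        return assign_protonation(sys_)
    raise TypeError(f"cannot interpret {type(peptide_pose)!r} as a peptide")


def hbond_conservation_ratio(pose, reference,
                             receptor: MolecularSystem) -> float:
    """Fraction of reference peptide-receptor H-bonds present in the pose.

    Defined as 1.0 when the reference complex has no hydrogen bonds.
    """
    ref_set = hbond_set(reference, receptor)
    if not ref_set:
        return 1.0
    pose_set = hbond_set(pose, receptor)
    return len(pose_set & ref_set) / len(ref_set)


def evaluate(ranked_poses, reference, receptor=None,
             bb_threshold: float = BACKBONE_RMSD_THRESHOLD,
             wp_threshold: float = WHOLE_RMSD_THRESHOLD) -> EvaluationReport:
    """Full evaluation of a ranked pose list against a reference pose."""
    bb = [rmsd(p, reference, "backbone") for p in ranked_poses]
    wp = [rmsd(p, reference, "whole") for p in ranked_poses]
    rank_bb = next((i + 1 for i, v in enumerate(bb) if v < bb_threshold),
                   None)
    rank_wp = next((i + 1 for i, v in enumerate(wp) if v < wp_threshold),
                   None)
    ratio = None
    if receptor is not None and ranked_poses:
        best = int(np.argmin(wp))
        ratio = hbond_conservation_ratio(ranked_poses[best], reference,
                                         receptor)
    return EvaluationReport(backbone_rmsd=bb, whole_rmsd=wp,
                            rank_first_correct_bb=rank_bb,
                            rank_first_correct_wp=rank_wp,
                            hbond_ratio=ratio)
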