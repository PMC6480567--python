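"""Synthetic receptor pockets with a planted peptide pose of known coordinates.

The receptor is a pseudo-atom cage, not a folded protein: hydrogen-bond
partner atoms are planted at ideal geometry opposite peptide donors and
acceptors, hydrophobic contact atoms opposite apolar sidechain carbons, and
a shell of cage atoms encloses the cavity.  Each generated complex is
certified at build time: the planted pose must score below the 5th
percentile of 1,000 random in-box placements under the surrogate scoring
function, so pose-recovery experiments are well-posed by construction
rather than by luck.

Pseudo-residue vocabulary (single-atom residues unless noted): ``HBA``
(acceptor, atom OA), ``HBD`` (donor, atoms ND + antecedent CD), ``HPH``
(hydrophobic carbon CH), ``CAG`` (cage carbon CC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import residues as rt
from .conformers import BACKBONE_ROTAMERS, CHI_ROTAMERS, nonbonded_pairs
from .dockcore import (Pose, PoseTopology, batch_field_score, build_grid,
                       fragment_topology, score_pose)
from .structures import (Atom, Chain, MolecularSystem, PeptideModel, Residue,
                         assign_protonation, hbond_acceptors, hbond_donors,
                         write_pdb)

CERTIFICATION_PLACEMENTS = 1000
CERTIFICATION_PERCENTILE = 95.0
HBOND_IDEAL_DISTANCE = 2.9
HYDROPHOBIC_DISTANCE = 3.4   # the minimum of the surrogate 8-4 potential
CAGE_STANDOFF = 4.0


class PocketGenerationError(RuntimeError):
    pass


@dataclass
class SyntheticComplex:
    receptor: MolecularSystem
    planted_peptide: Pose
    model: PeptideModel
    design: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def sequence(self) -> str:
        return self.model.sequence

    def reference_system(self) -> MolecularSystem:
        sys_ = self.model.to_system(self.planted_peptide.coords)
        return assign_protonation(sys_)

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pdb(self.receptor, out / "receptor.pdb")
        write_pdb(self.reference_system(), out / "reference.pdb")
        with open(out / "design.json", "w") as fh:
            json.dump(self.design, fh, indent=1, sort_keys=True)
        return {"receptor": str(out / "receptor.pdb"),
                "reference": str(out / "reference.pdb"),
                "design": str(out / "design.json")}


def make_pocket_system(sequence: str, n_contacts: int = 3, seed: int = 0,
                       max_retries: int = 10,
                       grid_spacing: float = 0.5) -> SyntheticComplex:
    """Build a certified pocket around a random peptide conformation.

    ``sequence`` must have 4-10 residues.  ``n_contacts`` hydrogen-bond
    partner atoms are planted at ideal distance/angle opposite peptide polar
    atoms; hydrophobic contacts are added opposite apolar sidechains, and a
    cage shell encloses the cavity.  Retries with a derived sub-seed when
    certification fails.
    """
    if not (4 <= len(sequence) <= 10):
        raise ValueError("sequence length must be 4-10 residues")
    last_fail = None
    for attempt in range(max_retries):
        sub_seed = (seed * 1009 + attempt * 7919) % (2 ** 31)
        try:
            return _build_once(sequence, n_contacts, seed, sub_seed,
                               grid_spacing)
        except PocketGenerationError as exc:
            last_fail = exc
    raise PocketGenerationError(
        f"pocket certification failed after {max_retries} attempts: "
        f"{last_fail}")


def _build_once(sequence, n_contacts, seed, sub_seed, grid_spacing):
    rng = np.random.default_rng(sub_seed)
    model = PeptideModel(sequence)
    torsions = _sample_torsions(model, rng)
    coords = model.coords(torsions)
    pep_sys = assign_protonation(model.to_system(coords))
    topo = PoseTopology(pep_sys, model=model)
    if _min_nonbonded(coords, topo) < 2.1:
        raise PocketGenerationError("self-clashing peptide conformation")

    centroid = coords.mean(axis=0)
    rec_residues: list[Residue] = []
    design_contacts = []
    occupied: list[np.ndarray] = []

    def clear(pt, pep_min=2.4, rec_min=2.6):
        if np.min(np.linalg.norm(coords - pt, axis=1)) < pep_min:
            return False
        return all(np.linalg.norm(pt - q) >= rec_min for q in occupied)

    # --- hydrogen-bond partners at ideal geometry -------------------------
    donors = hbond_donors(pep_sys)
    acceptors = hbond_acceptors(pep_sys)
    polar = ([("donor", di, ants) for di, ants in donors]
             + [("acceptor", ai, None) for ai in acceptors])
    # weight designed H-bond partners toward the C-terminal (seed) segment
    # (it anchors the whole reconstruction and must interact strongly and
    # specifically), with one partner on each later segment to guide growth
    n_res = len(model.seq3)
    try:
        from .fragmenter import fragment_peptide
        segs = fragment_peptide(sequence).segments   # C-terminal first
        regions = [set(range(s.start, s.end)) for s in segs]
    except Exception:
        regions = [set(range(max(0, n_res - 2), n_res)),
                   set(range(0, max(0, n_res - 2)))]
    queues = []
    assigned = set()
    def bb_first(members):
        # backbone partners pin the backbone trace; sidechain partners
        # tolerate chi rotations, so backbone polar atoms are preferred
        bb = [k for k in members
              if topo.names[polar[k][1]] in ("N", "O", "OXT")]
        sc = [k for k in members if k not in set(bb)]
        return [int(k) for k in rng.permutation(bb)] + \
            [int(k) for k in rng.permutation(sc)]

    for region in regions:
        members = [k for k in range(len(polar))
                   if int(topo.res_index[polar[k][1]]) in region]
        queues.append(bb_first(members))
        assigned |= set(members)
    leftovers = [k for k in range(len(polar)) if k not in assigned]
    queues.append(bb_first(leftovers))
    quotas = [n_contacts] + [1] * (len(queues) - 1)
    order = []
    for qi, q in enumerate(queues):
        take = min(quotas[qi], len(q))
        order += q[:take]
        queues[qi] = q[take:]
    while any(queues):
        for qi in range(len(queues)):
            if queues[qi]:
                order.append(queues[qi].pop(0))
    placed = 0
    planted_contacts = []   # (kind, pt, direction) for rim rings afterwards
    used_residues: set[int] = set()
    for k in order:
        if placed >= n_contacts:
            break
        kind, ai, ants = polar[int(k)]
        xyz = coords[ai]
        if kind == "donor":
            ant = coords[ants].mean(axis=0) if ants else centroid
            base_dir = xyz - ant
        else:
            neighbors = _bonded_neighbors(topo, ai)
            ant = coords[neighbors].mean(axis=0) if neighbors else centroid
            base_dir = xyz - ant
        base_dir = base_dir / (np.linalg.norm(base_dir) + 1e-12)
        # ideal approach first, small tilts as fallback when blocked
        success = False
        for direction in _tilted_directions(base_dir):
            pt = xyz + HBOND_IDEAL_DISTANCE * direction
            if not clear(pt):
                continue
            if any(np.linalg.norm(pt - prev_pt) < 4.2
                   for _, prev_pt, _ in planted_contacts):
                continue
            if kind == "donor":
                # backing atom defines the acceptor's lone-pair direction
                cb = pt + 1.40 * direction
                rec_residues.append(_pseudo("HBA", [("OA", "O", pt),
                                                    ("CB", "C", cb)]))
                occupied.append(pt)
            else:
                cd = pt + 1.45 * direction
                if not clear(cd, pep_min=2.4, rec_min=1.0):
                    continue
                rec_residues.append(_pseudo("HBD", [("ND", "N", pt),
                                                    ("CD", "C", cd)]))
                occupied.extend([pt, cd])
            success = True
            break
        if not success:
            continue
        used_residues.add(int(topo.res_index[ai]))
        planted_contacts.append((kind, pt, direction))
        design_contacts.append({"kind": kind, "peptide_atom": int(ai),
                                "point": [round(float(v), 3) for v in pt]})
        placed += 1
    if placed < n_contacts:
        raise PocketGenerationError(
            f"could only plant {placed}/{n_contacts} hydrogen-bond partners")
    # recess rims: rings of wall carbons around every partner, perpendicular
    # to its approach, so only the designed geometry reaches the well
    # without steric cost; added after all partners so they cannot block one
    # another
    for kind, pt, direction in planted_contacts:
        u1 = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(u1) < 1e-6:
            u1 = np.cross(direction, [0.0, 1.0, 0.0])
        u1 /= np.linalg.norm(u1)
        u2 = np.cross(direction, u1)
        for t in np.arange(0.0, 2 * np.pi - 1e-9, np.pi / 3):
            rim = pt + 3.0 * (np.cos(t) * u1 + np.sin(t) * u2) \
                - 0.3 * direction
            if clear(rim, pep_min=3.0, rec_min=2.2):
                rec_residues.append(_pseudo("RIM", [("CR", "C", rim)]))
                occupied.append(rim)

    # --- hydrophobic contacts opposite apolar sidechains ------------------
    n_phobic = 0
    for ri, resname in enumerate(model.seq3):
        for name in rt.HYDROPHOBIC_ATOMS.get(resname, [])[:2]:
            ai = model.atom_index(ri, name)
            direction = coords[ai] - centroid
            norm = np.linalg.norm(direction)
            if norm < 1e-6:
                continue
            pt = coords[ai] + HYDROPHOBIC_DISTANCE * direction / norm
            if clear(pt, pep_min=3.2):
                rec_residues.append(_pseudo("HPH", [("CH", "C", pt)]))
                occupied.append(pt)
                n_phobic += 1

    # --- counter-charges opposite charged sidechain tips: electrostatic
    # guidance (beyond hydrogen-bond range, so the designed H-bond count is
    # unaffected) for the charged residues of the growth segments ----------
    n_charge = 0
    charge_tips = {"LYS": ("NZ", "CHN"), "ARG": ("CZ", "CHN"),
                   "ASP": ("CG", "CHP"), "GLU": ("CD", "CHP")}
    for ri, resname in enumerate(model.seq3):
        tip = charge_tips.get(resname)
        if tip is None:
            continue
        name, partner = tip
        ai = model.atom_index(ri, name)
        direction = coords[ai] - centroid
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            continue
        pt = coords[ai] + 4.3 * direction / norm
        if clear(pt, pep_min=3.8):
            rec_residues.append(_pseudo(partner, [("CP", "C", pt)]))
            occupied.append(pt)
            n_charge += 1

    # --- cage shell: a molded wall around every peptide heavy atom, so the
    # cavity is snug against the planted conformation everywhere ----------
    n_cage = 0
    shell_dirs = _fibonacci_sphere(42)
    for ai in range(len(coords)):
        for direction in shell_dirs:
            pt = coords[ai] + CAGE_STANDOFF * direction
            if clear(pt, pep_min=3.4, rec_min=2.7):
                rec_residues.append(_pseudo("CAG", [("CC", "C", pt)]))
                occupied.append(pt)
                n_cage += 1

    for i, res in enumerate(rec_residues, start=1):
        res.seq_index = i
    receptor = MolecularSystem([Chain("R", rec_residues)], role="receptor")
    receptor = assign_protonation(receptor)

    planted = Pose(topology=topo, coords=coords.copy(), pose_id="planted",
                   res_offset=0)
    complex_ = SyntheticComplex(
        receptor=receptor, planted_peptide=planted, model=model,
        design={"sequence": sequence, "seed": seed, "sub_seed": sub_seed,
                "n_contacts": placed, "n_hydrophobic": n_phobic,
                "n_cage": n_cage, "n_charge": n_charge,
                "contacts": design_contacts},
        seed=seed)
    _certify(complex_, rng, grid_spacing)
    return complex_


def _certify(complex_: SyntheticComplex, rng, grid_spacing):
    """Fixture-quality certification; raises when the design is ill-posed.

    Checks, in order: every designed hydrogen bond registers at full weight
    and no incidental ones appear; every partner's open-approach target
    reproduces the designed geometry (the recess is clean); the planted
    pose beats >= 95% of random in-box placements; and the seed segment's
    planted sub-pose beats >= 98% of random placements of that fragment (a
    seed fragment that does not interact strongly and distinctively with
    the pocket cannot anchor a reconstruction).
    """
    grid = build_grid(complex_.receptor, complex_.planted_peptide,
                      spacing=grid_spacing)
    planted_bd = score_pose(grid, complex_.planted_peptide)
    n_contacts = complex_.design["n_contacts"]
    if planted_bd.counts.get("n_hbonds", 0) != n_contacts:
        raise PocketGenerationError(
            f"planted pose registers {planted_bd.counts.get('n_hbonds')} "
            f"full-weight hydrogen bonds, expected {n_contacts}")
    _certify_open_approaches(complex_, grid)
    coords = complex_.planted_peptide.coords
    cen = coords.mean(axis=0)
    centered = coords - cen
    P = CERTIFICATION_PLACEMENTS
    quats = rng.normal(size=(P, 4))
    rots = Rotation.from_quat(quats / np.linalg.norm(quats, axis=1,
                                                     keepdims=True))
    lo = grid.origin + 1.0
    hi = grid.box_max - 1.0
    trans = rng.uniform(lo, hi, size=(P, 3))
    batch = np.einsum("pij,aj->pai", rots.as_matrix(), centered) \
        + trans[:, None, :]
    random_scores = batch_field_score(grid, batch,
                                      complex_.planted_peptide.topology)
    threshold = np.percentile(random_scores,
                              100.0 - CERTIFICATION_PERCENTILE)
    if planted_bd.total >= threshold:
        raise PocketGenerationError(
            f"planted score {planted_bd.total:.2f} not below the "
            f"{CERTIFICATION_PERCENTILE:.0f}% certification threshold "
            f"({threshold:.2f})")
    seed_stats = _certify_seed_fragment(complex_, grid, rng)
    complex_.design["certification"] = {
        "planted_score": round(float(planted_bd.total), 3),
        "random_placement_threshold": round(float(threshold), 3),
        "n_hbonds_scored": planted_bd.counts.get("n_hbonds", 0),
        **seed_stats,
    }


def _certify_open_approaches(complex_: SyntheticComplex, grid,
                             tolerance: float = 0.9):
    """Each partner's open-approach target must hit the designed atom."""
    coords = complex_.planted_peptide.coords
    sites = [(s, u) for s, u in zip(grid.rec_acceptor_xyz,
                                    grid.rec_acceptor_dir)]
    sites += [(s, u) for s, u in zip(grid.rec_donor_xyz,
                                     grid.rec_donor_dir)]
    for ct in complex_.design["contacts"]:
        pt = np.array(ct["point"])
        atom_xyz = coords[ct["peptide_atom"]]
        match = min(sites, key=lambda su: np.linalg.norm(su[0] - pt))
        site, u = match
        if np.linalg.norm(site - pt) > 0.05:
            raise PocketGenerationError("designed partner missing from the "
                                        "grid's polar-site list")
        offset = float(np.linalg.norm(site + 2.9 * u - atom_xyz))
        if offset > tolerance:
            raise PocketGenerationError(
                f"open approach of a designed partner misses its atom by "
                f"{offset:.2f} A (recess not clean)")


def _certify_seed_fragment(complex_: SyntheticComplex, grid, rng,
                           n_placements: int = 500,
                           percentile: float = 98.0) -> dict:
    from .fragmenter import fragment_peptide
    from .dockcore import score_arrays
    try:
        seg0 = fragment_peptide(complex_.sequence).segments[0]
    except Exception:
        return {}
    sub_model = PeptideModel(complex_.sequence[seg0.start:seg0.end])
    sub_topo = fragment_topology(sub_model)
    full = complex_.model
    sub = np.array([complex_.planted_peptide.coords[
        full.atom_index(seg0.start + sub_model.atom_res[k],
                        sub_model.atom_names[k])]
        for k in range(sub_model.n_atoms)])
    planted_sub = score_arrays(grid, sub, sub_topo).total
    cen = sub.mean(axis=0)
    centered = sub - cen
    quats = rng.normal(size=(n_placements, 4))
    rots = Rotation.from_quat(quats / np.linalg.norm(quats, axis=1,
                                                     keepdims=True))
    trans = rng.uniform(grid.origin + 1.0, grid.box_max - 1.0,
                        size=(n_placements, 3))
    batch = np.einsum("pij,aj->pai", rots.as_matrix(), centered) \
        + trans[:, None, :]
    scores = batch_field_score(grid, batch, sub_topo)
    threshold = np.percentile(scores, 100.0 - percentile)
    if planted_sub >= threshold:
        raise PocketGenerationError(
            f"seed-fragment planted score {planted_sub:.2f} not below the "
            f"{percentile:.0f}% threshold ({threshold:.2f})")
    return {"seed_fragment_score": round(float(planted_sub), 3),
            "seed_fragment_threshold": round(float(threshold), 3)}


def _sample_torsions(model: PeptideModel, rng) -> np.ndarray:
    values = model.default_torsions()
    bb = BACKBONE_ROTAMERS[:2]   # extended-to-bent, recoverable by sampling
    for v, t in enumerate(model.torsions):
        if t.name == "phi":
            values[v] = bb[int(rng.integers(len(bb)))][0]
        elif t.name == "psi":
            values[v] = bb[int(rng.integers(len(bb)))][1]
        elif t.name == "carboxyl":
            values[v] = 0.0
        else:
            values[v] = CHI_ROTAMERS[int(rng.integers(len(CHI_ROTAMERS)))]
        values[v] += rng.uniform(-8.0, 8.0)
    return values


def _tilted_directions(base: np.ndarray, tilt_deg: float = 18.0):
    """The ideal approach direction followed by four slightly tilted ones."""
    from scipy.spatial.transform import Rotation as _R
    out = [base]
    perp = np.cross(base, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(base, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    perp2 = np.cross(base, perp)
    for axis in (perp, perp2):
        for sgn in (1.0, -1.0):
            rot = _R.from_rotvec(np.deg2rad(sgn * tilt_deg) * axis)
            out.append(rot.apply(base))
    return out


def _pseudo(resname: str, atoms: list[tuple[str, str, np.ndarray]]) -> Residue:
    res = Residue(name=resname, seq_index=0)
    for name, element, xyz in atoms:
        res.atoms.append(Atom(name=name, element=element,
                              coords=np.asarray(xyz, dtype=float)))
    return res


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _bonded_neighbors(topo: PoseTopology, ai: int) -> list[int]:
    if topo.model is None:
        return []
    return [j for i, j in topo.model.bonds if i == ai] + \
        [i for i, j in topo.model.bonds if j == ai]


def _min_nonbonded(coords: np.ndarray, topo: PoseTopology) -> float:
    pairs = topo.nb_pairs
    if len(pairs) == 0:
        return np.inf
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(d.min())


def perturb_pose(pose: Pose, magnitude: float, seed: int = 0) -> Pose:
    """Random rigid perturbation with heavy-atom RMSD ~= ``magnitude``.

    A random rotation about the centroid contributes a drawn fraction of the
    displacement and a random translation supplies the rest, so the realised
    RMSD tracks the requested magnitude closely.  ``magnitude=0`` is the
    identity; deterministic per seed.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    out = pose.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    coords = pose.coords
    cen = coords.mean(axis=0)
    frac = rng.uniform(0.3, 0.7)
    target_rot = magnitude * frac
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = np.deg2rad(10.0)
    for _ in range(6):
        rot = Rotation.from_rotvec(theta * axis)
        moved = rot.apply(coords - cen) + cen
        r = float(np.sqrt(((moved - coords) ** 2).sum(axis=1).mean()))
        if r < 1e-9:
            break
        theta *= min(target_rot / r, 4.0)
        theta = min(theta, np.pi)
    rot = Rotation.from_rotvec(theta * axis)
    moved = rot.apply(coords - cen) + cen
    r_rot = float(np.sqrt(((moved - coords) ** 2).sum(axis=1).mean()))
    t_norm = np.sqrt(max(magnitude ** 2 - r_rot ** 2, 0.0))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    out.coords = moved + t_norm * direction
    return out
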