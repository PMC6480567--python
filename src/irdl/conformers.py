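"""Fragment conformer generation by torsion sampling.

Torsion space is explored with a small backbone rotamer library (common
beta / polyproline-II / helical phi-psi combinations) crossed with staggered
sidechain rotamers, plus seeded random jitter.  Candidates are clash-filtered
and deduplicated at an internal (superposition-minimised) RMSD radius, ranked
by internal strain, and capped at ``max_n`` (default 200).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import kabsch_rmsd, kabsch_rmsd_many
from .structures import MolecularSystem, PeptideModel

#: (phi, psi) backbone rotamers: beta, polyproline II, alpha, extended, L-alpha
BACKBONE_ROTAMERS = [(-120.0, 130.0), (-75.0, 145.0), (-60.0, -45.0),
                     (-140.0, 150.0), (60.0, 45.0)]
CHI_ROTAMERS = [180.0, -60.0, 60.0]
CARBOXYL_ROTAMERS = [0.0, 90.0]

DEFAULT_CLASH_THRESHOLD = 2.0   # A, non-bonded heavy-atom minimum
DEFAULT_DEDUP_RADIUS = 0.5      # A, internal RMSD

# soft Lennard-Jones used for internal strain
_LJ_R0 = 3.4
_LJ_EPS = 0.3
_LJ_CAP = 3.0
_LJ_DMIN = 1.2


class EmptyConformerSetError(RuntimeError):
    pass


def nonbonded_pairs(graph: nx.Graph, n_atoms: int) -> np.ndarray:
    """Atom index pairs at bond-graph distance >= 3 (excludes 1-2 and 1-3)."""
    near = dict(nx.all_pairs_shortest_path_length(graph, cutoff=2))
    pairs = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)
             if j not in near.get(i, {})]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def soft_lj(d: np.ndarray, r0: float = _LJ_R0, eps: float = _LJ_EPS,
            cap: float = _LJ_CAP) -> np.ndarray:
    """Soft-core 8-4 Lennard-Jones, capped so near-clashes stay finite."""
    d = np.maximum(d, _LJ_DMIN)
    s4 = (r0 / d) ** 4
    return np.minimum(eps * (s4 * s4 - 2.0 * s4), cap)


def internal_energy(coords: np.ndarray, pairs: np.ndarray,
                    repulsive_only: bool = False) -> float:
    """Intramolecular strain: capped soft LJ over non-bonded heavy pairs.

    ``repulsive_only`` drops the attractive part, which is the strain
    measure used for ranking conformer ensembles (a compact conformer is
    not intrinsically better than an extended one).
    """
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    e = soft_lj(d)
    if repulsive_only:
        e = np.maximum(e, 0.0)
    return float(e.sum())


@dataclass
class Conformer:
    torsions: np.ndarray
    coords: np.ndarray
    energy: float


@dataclass
class ConformerSet:
    fragment_id: str
    model: PeptideModel
    conformers: list[Conformer] = field(default_factory=list)
    seed: int = 0

    def __len__(self):
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def coords_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.conformers])


def _candidate_sets(model: PeptideModel) -> list[list[float]]:
    """Per-torsion candidate values in model torsion order."""
    sets = []
    n = len(model.seq3)
    for t in model.torsions:
        if t.name == "phi":
            sets.append([bb[0] for bb in BACKBONE_ROTAMERS])
        elif t.name == "psi":
            sets.append([bb[1] for bb in BACKBONE_ROTAMERS])
        elif t.name == "carboxyl":
            sets.append(list(CARBOXYL_ROTAMERS))
        else:
            sets.append(list(CHI_ROTAMERS))
    return sets


def enumerate_conformers(fragment, max_n: int = 200, seed: int = 0,
                         clash_threshold: float = DEFAULT_CLASH_THRESHOLD,
                         dedup_radius: float = DEFAULT_DEDUP_RADIUS,
                         jitter: float = 8.0) -> ConformerSet:
    """Generate a clash-free, deduplicated, strain-ranked conformer ensemble.

    ``fragment`` is a sequence, :class:`PeptideModel` or peptide
    :class:`MolecularSystem`.  Backbone phi/psi pairs are sampled coherently
    from the rotamer library; chis from staggered rotamers; every torsion
    receives uniform jitter of +-``jitter`` degrees.  Deterministic for a
    fixed seed.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    model = _as_model(fragment)
    rng = np.random.default_rng(seed)
    pairs = nonbonded_pairs(model.bond_graph(), model.n_atoms)
    cand = _candidate_sets(model)
    n_combos = int(np.prod([len(c) for c in cand])) if cand else 1

    base_vectors: list[np.ndarray]
    budget = max(24 * max_n, 600)
    if model.n_torsions == 0:
        base_vectors = [np.zeros(0)]
    elif n_combos <= budget:
        base_vectors = [np.array(v) for v in itertools.product(*cand)]
    else:
        # backbone-first coverage: the backbone decides the overall shape,
        # so enumerate phi/psi/carboxyl combinations exhaustively at default
        # chis when that fits the budget, then fill with fully random draws
        bb = [k for k, t in enumerate(model.torsions)
              if t.name in ("phi", "psi", "carboxyl")]
        n_bb = int(np.prod([len(cand[k]) for k in bb])) if bb else 0
        base_vectors = []
        if 0 < n_bb <= budget:
            default = np.array([c[0] for c in cand])
            combos = list(itertools.product(
                *(range(len(cand[k])) for k in bb)))
            # most common rotamer combinations first (library order encodes
            # commonness), so the acceptance cap keeps the likely shapes
            combos.sort(key=lambda ix: (sum(ix), ix))
            for ix in combos:
                v = default.copy()
                v[bb] = [cand[k][i] for k, i in zip(bb, ix)]
                base_vectors.append(v)
        n_rand = budget - len(base_vectors)
        idx = [rng.integers(0, len(c), size=n_rand) for c in cand]
        base_vectors += [np.array([cand[k][idx[k][b]]
                                   for k in range(len(cand))])
                         for b in range(n_rand)]

    accepted: list[Conformer] = []
    acc_stack = None
    for base in base_vectors:
        tor = base + (rng.uniform(-jitter, jitter, size=base.shape)
                      if len(base) else 0.0)
        coords = model.coords(tor)
        if _has_clash(coords, pairs, clash_threshold):
            continue
        if accepted and kabsch_rmsd_many(
                coords, acc_stack).min() < dedup_radius:
            continue
        accepted.append(Conformer(
            tor, coords, internal_energy(coords, pairs,
                                         repulsive_only=True)))
        acc_stack = (coords[None] if acc_stack is None
                     else np.concatenate([acc_stack, coords[None]]))
        if len(accepted) >= 2 * max_n:
            break
    if not accepted:
        raise EmptyConformerSetError(
            f"no clash-free conformer found for {model.sequence!r}")
    order = sorted(range(len(accepted)),
                   key=lambda k: (accepted[k].energy, k))
    conformers = [accepted[k] for k in order[:max_n]]
    return ConformerSet(fragment_id=model.sequence, model=model,
                        conformers=conformers, seed=seed)


def _as_model(fragment) -> PeptideModel:
    if isinstance(fragment, PeptideModel):
        return fragment
    if isinstance(fragment, MolecularSystem):
        return PeptideModel(fragment.sequence)
    return PeptideModel(fragment)


def _has_clash(coords: np.ndarray, pairs: np.ndarray,
               threshold: float) -> bool:
    if len(pairs) == 0:
        return False
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return bool((d < threshold).any())


def relax_conformer(model: PeptideModel, conformer: Conformer,
                    steps: int = 100, step_deg: float = 10.0,
                    seed: int = 0) -> Conformer:
    """Torsion-space coordinate descent on internal strain.

    Bonded geometry stays ideal by construction (coordinates are regenerated
    from internal coordinates); the energy is non-increasing because moves
    are only accepted when they strictly improve it.  ``steps=0`` returns the
    conformer unchanged.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    pairs = nonbonded_pairs(model.bond_graph(), model.n_atoms)
    tor = conformer.torsions.copy()
    best_e = internal_energy(model.coords(tor), pairs)
    if steps == 0 or model.n_torsions == 0:
        return Conformer(tor, model.coords(tor), best_e)
    delta = step_deg
    for _ in range(steps):
        improved = False
        for k in range(len(tor)):
            for sgn in (+1.0, -1.0):
                trial = tor.copy()
                trial[k] += sgn * delta
                e = internal_energy(model.coords(trial), pairs)
                if e < best_e - 1e-12:
                    tor, best_e, improved = trial, e, True
                    break
        if not improved:
            delta *= 0.5
            if delta < 0.5:
                break
    return Conformer(tor, model.coords(tor), best_e)
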