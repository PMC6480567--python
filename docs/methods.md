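# Methods

This note documents the models, algorithms and numerical choices behind
`irdl`, in the order the pipeline uses them.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Molecular model

Peptides are represented at heavy-atom resolution with idealised internal
coordinates.  A sequence plus a torsion vector — φ for residues 2..n, ψ
for residues 1..n−1, sidechain χ angles, and one C-terminal carboxyl
rotation — generates Cartesian coordinates by natural-extension-reference-
frame placement; ω amide torsions are fixed trans (180°) and proline
contributes neither φ nor χ (its ring is built with fixed endo-pucker
internal coordinates).  This torsion vector *is* the rotatable-bond
inventory: `count_rotatable_bonds` counts exactly the sampled torsions.
The convention is a documented choice; published per-peptide torsion
counts never state one, and ours reproduces plausible magnitudes (a
poly-Ala 5-mer has 9; appending an alanine adds 2).

Bond lengths and angles are standard idealised values; aromatic rings and
the proline ring close to within 0.07 Å of their ideal bond lengths, which
is well inside the bond-perception threshold used by the topology check
(1.25 × the covalent-radius sum).  Hydrogens are implicit everywhere:
hydrogen-bond donors are nitrogen/oxygen heavy atoms with an implied
proton, and the donor angle is measured at the donor against its bonded
antecedent(s).

Protonation at pH 7.4 assigns Asp/Glu −1, Lys/Arg +1, neutral His, +1/−1
free termini (simple pKa rules cover other pH values).  Partial charges
start from a coarse per-element baseline and are shifted uniformly within
each residue so the residue total equals its formal charge — a
self-consistent table for a surrogate electrostatic term, not a force
field.

## Fragmentation

Segments must carry at most 10 rotatable bonds (counted as free fragments)
and must not start with Tyr, Cys, Ser, Thr, Asn or Gln, whose nucleophilic
sidechains would compete with the backbone amine in the modelled
amide-forming reaction; the whole-peptide N-terminus is exempt because it
never receives a bond.  A dynamic program finds the minimal number of
segments; among minimal tilings the C-terminal (seed) segment's
rotatable-bond count is maximised — the seed anchors the whole
reconstruction and benefits from the most interaction content — with
lexicographically earliest boundaries as the final deterministic
tie-break.  Single-residue segments are allowed only when the rules force
them.  The implementation is checked against exhaustive tiling enumeration
for every sequence up to length 6 over a six-letter test alphabet and a
large seeded sample of longer ones.

## Conformer generation

Fragment ensembles come from a backbone rotamer library (β, polyproline
II, α, extended, left-handed α) crossed with staggered χ rotamers and a
±8° uniform jitter, clash-filtered at 2.0 Å between non-bonded heavy atoms
and deduplicated at 0.5 Å superposition-minimised internal RMSD.  When the
full torsion product exceeds the sampling budget, backbone combinations
are enumerated exhaustively at default χ (ordered by rotamer commonness,
so the likely bound-peptide shapes survive the acceptance cap) and the
remainder of the budget is filled with random draws.  Ensembles are capped
at `max_n` (default 200) and ranked by repulsive-only internal strain —
a compact conformer is not intrinsically better than an extended one.
Everything is deterministic under the seed.

## Scoring

The receptor is precomputed on a Cartesian grid (default spacing 0.4 Å)
over the cavity box: the bound-peptide reference's bounding box inflated
by a 5 Å margin.  Fields: a soft-core 8–4 Lennard-Jones steric field
(r₀ = 3.4 Å, ε = 0.3, per-pair cap 3.0; distances floored at 1.2 Å), a
screened-Coulomb potential (distance-dependent dielectric 4r, distances
floored at 1.5 Å), and distance-well hydrogen-bond affinity fields from
receptor donors and acceptors.  Synthetic cavity-wall pseudo-atoms are
purely repulsive and harder (cap 25) so the boundary cannot be crossed
cheaply; a soft variant of the steric field (ordinary caps) drives the
placement-filter stage so near-miss placements survive into refinement.

A pose score is the weighted sum of: trilinearly interpolated steric and
electrostatic terms; a pairwise hydrogen-bond term (distance well with
full weight at 2.75–3.05 Å and linear ramps to 2.3/3.5 Å, times a donor-
angle factor linear between 90° and 120°) evaluated against the receptor's
donor/acceptor atoms so that angles apply and individual bonds can be
counted; and intramolecular strain (capped soft LJ over pairs at bond-graph
distance ≥ 3).  Atoms outside the box incur a 50-point boundary penalty.
Default weights are 1 (steric), 2 (H-bond), 0.5 (electrostatics), 0.25
(strain).  The final-ranking weight set doubles the H-bond emphasis again
(to 4) and adds a burial bonus of 0.05 per receptor-contact count (capped
at 8 contacts per atom within 4.5 Å).  Scores are dimensionless and lower
is better; the function reproduces the *logic* of a docking score, and
parity with any proprietary engine is explicitly not claimed.

## Pose search

Seed-segment docking proceeds in stages, all deterministic under the run
seed: (1) random rigid placements inside the box plus polar-site-targeted
placements that put a peptide donor/acceptor at a receptor partner's
ideal distance along its open approach direction with the antecedent
aligned; (2) two-site and three-site matches, which map pairs/triplets of
distance-compatible peptide polar atoms onto receptor partner sites
(three-site matches pin the placement completely); (3) fast filtering on
the grid fields with spatial-diversity selection, plus a guaranteed
refinement slot for the best placement of every (site, polar atom)
pairing; (4) greedy coordinate descent over rigid-body and torsion
coordinates against the field objective, then an exact-score polish.
Results are deduplicated at 1.0 Å pose RMSD and ranked.

Open approach directions come from chemistry where possible (donor → along
its antecedent axis; acceptor → away from its bonded neighbours) and from
local receptor bulk otherwise.

## Growth steps

The incoming fragment's C-terminal carboxyl O(H) is replaced by Cl (acid
chloride; heavy-atom count unchanged).  With the anchor rigid and the
junction geometry ideal, the fragment placement is fully determined by the
anchor residue's φ and the orientation of its free amine (the anchor's
first-residue ψ, which nothing constrained during earlier steps); both are
enumerated on grids (30°/72° with jitter) per conformer, realised by a
least-squares fit of the fragment's carbonyl triad onto the ideal amide
frame.  Candidates are filtered on grid fields plus anchor sterics,
refined under the proximity restraint (the carbonyl C may approach the
amine down to bond distance — placements are constructed at ideal amide
geometry and sterics prevent collapse — and is harmonically restrained
beyond 4.0 Å), and fused: the Cl leaves, the carbonyl triad is
snapped onto the ideal frame (bond 1.33 Å, trans-planar ω, ideal angles;
the φ freedom is scanned for the least disruptive, least clashing
solution), and the amine is repositioned to the enumerated orientation —
the two junction residues are then relaxed in Cartesian space (moves
accepted only when the pose score strictly improves and every touched bond
stays within 0.12 Å).

Linked poses whose distance-perceived bond graph is not isomorphic
(element-coloured) to the expected peptide graph are removed.  Survivors
are clustered by average-linkage hierarchical clustering on pairwise
heavy-atom RMSD into at most 15 clusters (identical geometries never
split); each representative (best covalent score in its cluster) then
receives a whole-peptide torsion-space relaxation against the rigid
receptor — the peptide fully flexible, as in the docking stages — with
backbone (φ, ψ) rotamer-hop and sidechain χ-hop passes in between: a hop
is applied in torsion space, the whole pose is rigidly re-fitted onto its
previous coordinates so anchored parts stay put, and it is accepted only
when the score strictly improves (small-step descent cannot cross rotamer
barriers).  The covalent score is the unweighted mean of the
anchor's, the fragment's, and the linked pose's score-in-place values.
Representatives are rescored in place with the standard weight set (the
final-ranking weights were deliberately not used at intermediate steps)
and the top-10 beam continues to the next segment.  After the final
segment, survivors are relaxed once more and rescored with the
final-ranking weight set; ties break on pose identifier for
reproducibility.

Beam selection is top-k (k = 10) by default.  Two reference-aware modes
support protocol-faithful benchmarking when a reference pose exists (the
method itself never requires one): ``oracle`` keeps all poses from rank 1
through the best-RMSD pose, capped at the configured beam maximum, and
``oracle_topk`` keeps the top-k beam with the best-RMSD pose guaranteed
retained.  Growth budgets adapt to the beam width — a narrow beam receives
proportionally more candidates per anchor — so every step explores a
roughly constant number of candidates.

## Synthetic fixtures

`make_pocket_system` draws a random extended-to-bent peptide conformation
(backbone from the β/polyproline-II rotamers ± 8°, staggered χ ± 8°),
rejects self-clashing draws, and builds a pseudo-atom receptor around it:

* exactly `n_contacts` hydrogen-bond partner atoms at 2.9 Å along the
  ideal donor/acceptor directions, preferring backbone polar atoms of the
  C-terminal (seed) segment — backbone partners pin the backbone trace,
  and the seed fragment must interact strongly and specifically with the
  pocket to anchor the reconstruction; partner sites are kept ≥ 4.2 Å
  apart so the triplet is geometrically non-degenerate;
* a ring of wall atoms (radius 3 Å) around each partner perpendicular to
  its approach, so only the designed geometry reaches the well without
  steric cost;
* hydrophobic contact atoms at 3.4 Å (the minimum of the surrogate 8–4
  potential) opposite apolar sidechain carbons, and counter-charge atoms
  at 4.3 Å opposite charged sidechain tips (beyond hydrogen-bond range, so
  the designed bond count is unaffected);
* a molded shell of purely repulsive wall atoms 4.0 Å from every peptide
  heavy atom, forming a snug cavity.

Each complex is certified at build time, with sub-seed retries: designed
bonds must register at full weight and exact count; every partner's open
approach must hit its designed atom; the planted pose must beat ≥ 95 % of
1,000 random in-box placements; and the seed segment's planted sub-pose
must beat ≥ 98 % of random placements of that fragment.  These checks make
"recovery is well-posed" a property of the fixture rather than of luck.

What the fixtures do *not* emulate: folded protein receptors with backbone
context, induced fit, explicit water, crowded or solvent-exposed
interfaces, and competing near-native binding sites.  Passing the recovery
benchmark therefore demonstrates that the protocol logic — fragmentation,
seeded docking, covalent growth, clustering, rescoring, ranking — works
end to end on well-posed cavities; it does not predict accuracy on
crystallographic complexes.

## Evaluation

RMSD follows the docking convention: heavy atoms only, computed in the
fixed receptor frame *without* superposition.  Chemically equivalent
sidechain atoms (Phe/Tyr ring CD/CE pairs swapped jointly, Asp OD1/OD2,
Glu OE1/OE2, Arg NH1/NH2) are matched per residue to minimise the result;
the implementation is verified against brute-force enumeration of all swap
assignments.  A pose is a correct solution below 2 Å backbone
({N, CA, C, O}) or 3 Å whole-peptide RMSD; `rank_first_correct` reports
the 1-based rank of the first pose under each threshold.  Hydrogen bonds
are heavy-atom pairs at ≤ 3.5 Å with a donor angle ≥ 120° (both
configurable); the conservation ratio is the fraction of the reference
complex's peptide–receptor bonds present in a pose, defined as 1 when the
reference has none.  Sidechain–receptor and backbone–receptor bonds are
both counted.

## Problem sizes and degenerate inputs

The recovery benchmark uses ten sequences of 5–8 residues (2–3 segments,
three designed contacts, seeds derived consecutively from the master
seed), oracle retention capped at a beam of 10 — the retention the
protocol itself prescribes when a reference exists, with the final ranking
blind to it — 120 seed-segment conformers, 48 per growth step, and
the search budgets recorded in `RunConfig`; these defaults keep a full
replicate around a minute on one CPU and are all configurable.  Degenerate
cases behave as follows: a single-segment plan reduces the pipeline to
seed docking plus final rescoring; a fragment with no sampled torsions
yields exactly one conformer; an empty reference hydrogen-bond set gives a
conservation ratio of 1; clustering of n < k poses returns n
representatives; identical geometries never split into separate
representatives.

## Known limitations

Growth is strictly C→N; peptides that anchor through their N-terminus are
out of reach, as is bidirectional growth.  The receptor is rigid
throughout — no induced fit.  Scoring is a surrogate: score values are not
comparable across receptors and carry no physical energy scale.  Seed
placement remains the critical step: when the C-terminal segment's pose is
not represented in the beam, later steps cannot recover, which is why the
fixture generator concentrates designed interactions on the seed segment
and certifies seed distinctiveness.  Ring conformations beyond the fixed
proline pucker are not sampled.
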