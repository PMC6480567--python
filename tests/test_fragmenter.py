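"""Fragmentation rules, minimal tilings, and the brute-force oracle."""

import itertools

import numpy as np
import pytest

from irdl import residues as rt
from irdl.fragmenter import (InfeasibleFragmentationError,
                             MAX_SEGMENT_ROTATABLE_BONDS, FragmentationPlan,
                             Segment, fragment_peptide, validate_plan)
from irdl.structures import count_rotatable_bonds

FORBIDDEN_ONE = {rt.THREE_TO_ONE[r] for r in rt.FORBIDDEN_NTERM}


def brute_force_min_segments(seq: str):
    """Enumerate every tiling; return the minimal rule-satisfying count."""
    n = len(seq)
    counts = {(a, b): count_rotatable_bonds(seq[a:b])
              for a in range(n) for b in range(a + 1, n + 1)}
    allowed_start = [i == 0 or seq[i] not in FORBIDDEN_ONE
                     for i in range(n)]
    best = None
    for mask in range(2 ** (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1)
                        if (mask >> i) & 1] + [n]
        segs = list(zip(bounds, bounds[1:]))
        if best is not None and len(segs) >= best:
            continue
        if any(counts[s] > MAX_SEGMENT_ROTATABLE_BONDS for s in segs):
            continue
        if any(not allowed_start[a] for a, _ in segs):
            continue
        best = len(segs)
    return best


def test_short_sequence_single_segment():
    plan = fragment_peptide("AAAAA")   # 9 rotatable bonds fits one segment
    assert plan.n_segments == 1


def test_long_polyalanine_splits():
    plan = fragment_peptide("A" * 12)  # 23 rotatable bonds cannot fit one
    assert plan.n_segments >= 2
    assert all(s.rotatable_bond_count <= MAX_SEGMENT_ROTATABLE_BONDS
               for s in plan.segments)


def test_segments_tile_sequence():
    for seq in ("GAKDF", "AGLDKAFE", "A" * 12, "KWKWKW"):
        plan = fragment_peptide(seq)
        rebuilt = "".join(s.subsequence(seq)
                          for s in plan.segments_n_to_c())
        assert rebuilt == seq


def test_boundary_avoids_forbidden_nterm():
    """A minimal cut landing on Ser shifts away from it."""
    # ASAAAAAAAAAA needs >= 2 segments; a cut at position 1 (Ser) is barred
    seq = "ASAAAAAAAAAA"
    plan = fragment_peptide(seq)
    for s in plan.segments:
        if s.start > 0:
            assert seq[s.start] not in FORBIDDEN_ONE


def test_whole_peptide_nterm_exempt():
    """The peptide's own N-terminal residue may be nucleophilic."""
    plan = fragment_peptide("SAAAA")
    assert plan.segments_n_to_c()[0].start == 0
    assert validate_plan(plan) == []


def test_infeasible_fragmentation_reports_positions():
    # every interior position is a forbidden type and one segment is too big
    seq = "KSSSSSSSSSSS"
    with pytest.raises(InfeasibleFragmentationError) as err:
        fragment_peptide(seq)
    assert err.value.blocking


def test_matches_brute_force_on_random_sample():
    rng = np.random.default_rng(11)
    letters = "AGSKPW"
    for _ in range(150):
        n = int(rng.integers(2, 11))
        seq = "".join(letters[i] for i in rng.integers(0, len(letters), n))
        expected = brute_force_min_segments(seq)
        if expected is None:
            with pytest.raises(InfeasibleFragmentationError):
                fragment_peptide(seq)
        else:
            plan = fragment_peptide(seq)
            assert plan.n_segments == expected
            assert validate_plan(plan) == []


def test_tie_break_maximises_seed_segment():
    """Among minimal tilings the C-terminal segment carries the most
    rotatable bonds (the seed fragment should interact most strongly)."""
    seq = "A" * 10    # many 2-segment tilings exist
    plan = fragment_peptide(seq)
    assert plan.n_segments == 2
    best_possible = 0
    for cut in range(1, len(seq)):
        a = count_rotatable_bonds(seq[:cut])
        b = count_rotatable_bonds(seq[cut:])
        if a <= 10 and b <= 10:
            best_possible = max(best_possible, b)
    assert plan.segments[0].rotatable_bond_count == best_possible


def test_validate_plan_flags_violations():
    plan = FragmentationPlan(sequence="AAASAA", segments=[
        Segment(3, 6, 12),    # wrong count and rule-a breach, starts at Ser
        Segment(0, 3, 5),
    ])
    violations = validate_plan(plan)
    assert any("rule-a" in v for v in violations)
    assert any("rule-b" in v for v in violations)


def test_plan_emitted_by_fragmenter_is_self_consistent():
    for seq in ("GAKDF", "ADKWG", "AGLDKAFE"):
        assert validate_plan(fragment_peptide(seq)) == []
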