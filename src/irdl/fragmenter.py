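"""Peptide fragmentation for C-terminus-to-N-terminus reconstruction.

A peptide is split into the minimal number of contiguous segments such that
(a) every segment has at most 10 rotatable bonds (counted as a free fragment)
and (b) no segment other than the whole-peptide N-terminal one starts with a
nucleophilic-sidechain residue (Tyr, Cys, Ser, Thr, Asn, Gln), which would
compete with the backbone amine during in-silico amide formation.  Segments
are ordered C-terminal first, matching the build order of the docking
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import residues as rt
from .structures import _as_three_letter, count_rotatable_bonds

MAX_SEGMENT_ROTATABLE_BONDS = 10


class InfeasibleFragmentationError(ValueError):
    """No tiling satisfies the fragmentation rules."""

    def __init__(self, sequence: str, blocking: list[int]):
        self.blocking = blocking
        super().__init__(
            f"no valid fragmentation of {sequence!r}: every candidate "
            f"boundary is blocked at positions {blocking} "
            f"(1-based, forbidden N-terminal residue types)")


@dataclass(frozen=True)
class Segment:
    """Half-open residue range [start, end) with its rotatable-bond count."""
    start: int
    end: int
    rotatable_bond_count: int

    def subsequence(self, sequence: str) -> str:
        return sequence[self.start:self.end]


@dataclass
class FragmentationPlan:
    sequence: str
    segments: list[Segment] = field(default_factory=list)  # C-terminal first
    forbidden_nterm: frozenset = rt.FORBIDDEN_NTERM

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segments_n_to_c(self) -> list[Segment]:
        return list(reversed(self.segments))

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "segments": [
                {"start": s.start, "end": s.end,
                 "rotatable_bonds": s.rotatable_bond_count}
                for s in self.segments],
            "forbidden_nterm": sorted(self.forbidden_nterm),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _boundary_allowed(seq3: list[str], pos: int) -> bool:
    """May a segment start at residue index ``pos``?

    The whole-peptide N-terminus (pos 0) is exempt from the nucleophile rule:
    it never receives an incoming bond.
    """
    return pos == 0 or seq3[pos] not in rt.FORBIDDEN_NTERM


def fragment_peptide(sequence) -> FragmentationPlan:
    """Split ``sequence`` into the minimal number of rule-satisfying segments.

    Among minimal tilings the C-terminal (seed) segment's rotatable-bond
    count is maximised — the seed fragment anchors the whole reconstruction
    and benefits from the most interaction content — with lexicographically
    earliest boundaries as the final deterministic tie-break.
    """
    seq3 = _as_three_letter(sequence)
    seq1 = "".join(rt.THREE_TO_ONE[r] for r in seq3)
    n = len(seq3)
    if n < 2:
        raise ValueError("sequence must have length >= 2")

    # g[i] = minimal number of segments tiling the suffix [i, n), or None
    g: list[int | None] = [None] * (n + 1)
    g[n] = 0
    for i in range(n - 1, -1, -1):
        if not _boundary_allowed(seq3, i):
            continue
        best = None
        for j in range(i + 1, n + 1):
            if _segment_rotbonds(seq3, i, j) > MAX_SEGMENT_ROTATABLE_BONDS:
                break  # counts grow monotonically with segment length
            if g[j] is not None:
                cand = 1 + g[j]
                best = cand if best is None else min(best, cand)
        g[i] = best
    if g[0] is None:
        blocking = [i + 1 for i in range(1, n)
                    if not _boundary_allowed(seq3, i)]
        raise InfeasibleFragmentationError(seq1, blocking)

    # enumerate minimal tilings (only edges consistent with g), pick best
    tilings: list[tuple[int, ...]] = []

    def extend(i: int, cuts: tuple[int, ...]):
        if i == n:
            tilings.append(cuts)
            return
        for j in range(i + 1, n + 1):
            if _segment_rotbonds(seq3, i, j) > MAX_SEGMENT_ROTATABLE_BONDS:
                break
            if j == n:
                if g[i] == 1:
                    extend(j, cuts)
            elif g[j] is not None and g[i] == 1 + g[j]:
                extend(j, cuts + (j,))

    extend(0, ())

    def key(cuts):
        last_start = cuts[-1] if cuts else 0
        return (-_segment_rotbonds(seq3, last_start, n), cuts)

    cuts = min(tilings, key=key)
    bounds = [0, *cuts, n]
    segments = [Segment(a, b, _segment_rotbonds(seq3, a, b))
                for a, b in zip(bounds, bounds[1:])]
    return FragmentationPlan(sequence=seq1, segments=list(reversed(segments)))


def _segment_rotbonds(seq3: list[str], start: int, end: int) -> int:
    return count_rotatable_bonds(seq3[start:end])


def validate_plan(plan: FragmentationPlan, sequence=None) -> list[str]:
    """Check a plan against the fragmentation rules; empty list means valid."""
    seq1 = plan.sequence if sequence is None else \
        "".join(rt.THREE_TO_ONE[r] for r in _as_three_letter(sequence))
    seq3 = _as_three_letter(seq1)
    violations: list[str] = []
    segs = plan.segments_n_to_c()
    covered = [(s.start, s.end) for s in segs]
    tiled = []
    for a, b in covered:
        tiled.extend(range(a, b))
    if tiled != list(range(len(seq3))):
        violations.append("tiling: segments do not tile the sequence exactly")
    for k, s in enumerate(plan.segments):
        actual = _segment_rotbonds(seq3, s.start, s.end) \
            if 0 <= s.start < s.end <= len(seq3) else None
        if s.rotatable_bond_count > MAX_SEGMENT_ROTATABLE_BONDS:
            violations.append(
                f"rule-a: segment {k} has {s.rotatable_bond_count} rotatable "
                f"bonds (> {MAX_SEGMENT_ROTATABLE_BONDS})")
        if actual is not None and actual != s.rotatable_bond_count:
            violations.append(
                f"count: segment {k} declares {s.rotatable_bond_count} "
                f"rotatable bonds, recount gives {actual}")
        if s.start > 0 and seq3[s.start] in plan.forbidden_nterm:
            violations.append(
                f"rule-b: segment {k} starts with forbidden N-terminal "
                f"residue {seq3[s.start]} at position {s.start + 1}")
    return violations
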