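"""Motif schedules: the tiling of a coiled coil into phase-rate blocks.

The parametric builder describes a coiled coil as a contiguous tiling of
"motifs", each linking structurally equivalent residues.  A canonical motif
is 7 residues containing two helical turns (phase rate 2/7 turn per residue,
slightly faster than the intrinsic 1/3.617, the excess wound into left-handed
supercoil twist).  Two non-canonical motifs accommodate register defects:

* a **29-residue motif** (four heptads merged plus the extra skip residue)
  with 8 helical turns, which locally unwinds the supercoil at a skip;
* a **27-residue motif** (four heptads merged minus one deleted residue)
  with 8 helical turns, which locally overwinds it at a deletion.

Both span two heptads upstream of the defect-containing heptad and one
downstream, so a skip at E1582 yields the 29-motif covering F1565–V1594
(exclusive of the V1594 heptad start) and the K1617 deletion yields the
27-motif covering L1601–L1629 (exclusive), with canonical register restored
beyond each block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from myotail.register import HeptadAssignment

CANONICAL_LENGTH = 7
CANONICAL_TURNS = 2.0
MERGED_TURNS = 8.0


class UnsupportedScheduleError(ValueError):
    """Raised when skips/deletions cannot be tiled into a motif schedule."""


@dataclass(frozen=True)
class Motif:
    """A contiguous block of residues sharing one helix phase rate.

    ``length`` counts physical residues (a skip residue counts, a deleted
    one does not); ``helical_turns`` is the number of helix turns the motif
    contains, so the local phase rate is ``360 * helical_turns / length``
    degrees per residue.  Edge fillers shorter than a heptad carry the
    canonical rate via fractional ``helical_turns``.
    """

    start_residue: int
    length: int
    helical_turns: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("motif length must be >= 1")
        if self.helical_turns <= 0:
            raise ValueError("helical_turns must be positive")

    @property
    def phase_rate_deg(self) -> float:
        """Helix phase advance per residue within this motif, degrees."""
        return 360.0 * self.helical_turns / self.length


@dataclass(frozen=True)
class MotifSchedule:
    """Ordered, contiguous motif tiling of the modeled region."""

    motifs: tuple[Motif, ...]
    mode: str  # "skip-del" | "canonical-throughout"

    @property
    def total_length(self) -> int:
        """Total physical residue count covered by the schedule."""
        return sum(m.length for m in self.motifs)

    @property
    def noncanonical(self) -> tuple[Motif, ...]:
        """Motifs other than canonical heptads and edge fillers."""
        return tuple(m for m in self.motifs if m.length > CANONICAL_LENGTH)

    def per_residue_rates(self) -> "list[float]":
        """Phase rate (deg/residue) for every physical residue, in chain order."""
        rates: list[float] = []
        for m in self.motifs:
            rates.extend([m.phase_rate_deg] * m.length)
        return rates


def _tile_canonical(ids: Sequence[int], first_a: int | None) -> list[Motif]:
    """Tile ``ids`` with heptads (N=2), aligning full heptads on ``first_a``."""
    motifs: list[Motif] = []
    n = len(ids)
    lead = 0
    if first_a is not None and first_a in ids:
        lead = list(ids).index(first_a)
    if lead:
        motifs.append(Motif(ids[0], lead, CANONICAL_TURNS * lead / CANONICAL_LENGTH))
    pos = lead
    while n - pos >= CANONICAL_LENGTH:
        motifs.append(Motif(ids[pos], CANONICAL_LENGTH, CANONICAL_TURNS))
        pos += CANONICAL_LENGTH
    if pos < n:
        tail = n - pos
        motifs.append(Motif(ids[pos], tail, CANONICAL_TURNS * tail / CANONICAL_LENGTH))
    return motifs


def make_motif_schedule(
    assignment: HeptadAssignment,
    skips: Iterable[int] | None = None,
    deletions: Iterable[int] = (),
    mode: str = "skip-del",
) -> MotifSchedule:
    """Build the motif tiling for a chain with optional skips and deletions.

    Parameters
    ----------
    assignment:
        Wild-type heptad assignment covering the modeled region (including
        any residues that the deletion removes).
    skips:
        Skip residue ids; defaults to ``assignment.skip_positions``.
    deletions:
        Wild-type ids of deleted residues (absent from the physical chain).
    mode:
        ``"skip-del"`` emits a 29-residue motif around each skip and a
        27-residue motif around each deletion (8 helical turns each);
        ``"canonical-throughout"`` emits only canonical heptads, letting the
        register shift between a skip and a downstream deletion so the two
        defects cancel.

    Raises
    ------
    UnsupportedScheduleError
        If a defect sits too close to the region edge to merge four heptads,
        or two defects are closer than one motif span in ``skip-del`` mode.
    """
    if mode not in ("skip-del", "canonical-throughout"):
        raise ValueError(f"unknown mode {mode!r}")
    skips = tuple(assignment.skip_positions if skips is None else sorted(skips))
    deletions = tuple(sorted(deletions))
    wt_ids = list(assignment.residue_ids)
    for d in deletions:
        if d not in wt_ids:
            raise ValueError(f"deletion {d} outside the modeled region")
    physical = [r for r in wt_ids if r not in deletions]
    a_positions = [r for r in wt_ids if assignment.letters.get(r) == "a"]
    first_a = a_positions[0] if a_positions else None

    if mode == "canonical-throughout":
        return MotifSchedule(tuple(_tile_canonical(physical, first_a)), mode)

    # skip-del: one merged block per defect, spanning heptads [h-2, h+1]
    # where h is the heptad containing the defect.
    blocks: list[tuple[int, int]] = []  # (start WT id, end WT id) inclusive
    for site in sorted(skips + deletions):
        below = [a for a in a_positions if a <= site]
        if len(below) < 3 or len([a for a in a_positions if a > site]) < 2:
            raise UnsupportedScheduleError(
                f"defect at {site} too close to the region edge to merge four heptads"
            )
        start = below[-3]
        end_a = [a for a in a_positions if a > site][1]
        blocks.append((start, end_a - 1))
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 <= e1:
            raise UnsupportedScheduleError(
                f"defects in blocks {s1}-{e1} and {s2}-{e2} are closer than one motif span"
            )

    motifs: list[Motif] = []
    cursor = 0  # index into `physical`
    for start, end in blocks:
        block_ids = [r for r in physical if start <= r <= end]
        pre_ids = [r for r in physical[cursor:] if r < start]
        if pre_ids:
            motifs.extend(_tile_canonical(pre_ids, first_a if cursor == 0 else pre_ids[0]))
        motifs.append(Motif(block_ids[0], len(block_ids), MERGED_TURNS))
        cursor = physical.index(block_ids[-1]) + 1
    rest = physical[cursor:]
    if rest:
        motifs.extend(_tile_canonical(rest, rest[0] if cursor else first_a))

    schedule = MotifSchedule(tuple(motifs), mode)
    if schedule.total_length != len(physical):
        raise AssertionError("motif tiling does not cover the chain")  # pragma: no cover
    return schedule
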