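"""Heptad register assignment and wild-type-numbered sequence bookkeeping.

Coiled-coil sequences follow a 7-residue quasi-repeat labelled ``a``–``g``.
The myosin rod interrupts this repeat with "skip" residues: an extra residue
at which the cyclic propagation pauses for one position (the skip residue
itself carries the label ``"skip"``).  Deletion mutants are represented by a
:class:`NumberedSequence` whose wild-type numbering retains an explicit gap
at the deleted position; profiles and schedules index by that numbering
throughout, so results for mutants line up residue-for-residue with the
wild type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

HEPTAD_LETTERS = "abcdefg"


class RegisterConflictError(ValueError):
    """Raised when register anchors imply contradictory heptad phases."""


class MutationError(ValueError):
    """Raised when a mutation spec does not match the sequence."""


@dataclass(frozen=True)
class NumberedSequence:
    """A one-letter sequence with explicit wild-type residue numbering.

    ``numbering[i]`` is the wild-type residue id of ``seq[i]``.  Deleting a
    residue removes it from both, leaving a gap in the numbering; numbering
    is therefore strictly increasing but not necessarily contiguous.
    """

    seq: str
    numbering: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.numbering):
            raise ValueError("sequence and numbering lengths differ")
        if any(b <= a for a, b in zip(self.numbering, self.numbering[1:])):
            raise ValueError("numbering must be strictly increasing")

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, resid: int) -> str:
        """One-letter code at wild-type position ``resid``."""
        try:
            return self.seq[self.numbering.index(resid)]
        except ValueError:
            raise KeyError(f"residue {resid} absent (deleted or out of range)") from None

    @property
    def gaps(self) -> tuple[int, ...]:
        """Wild-type positions missing from the numbering (deletions)."""
        full = range(self.numbering[0], self.numbering[-1] + 1)
        present = set(self.numbering)
        return tuple(r for r in full if r not in present)

    @classmethod
    def from_string(cls, seq: str, start: int = 1) -> "NumberedSequence":
        return cls(seq, tuple(range(start, start + len(seq))))


@dataclass(frozen=True)
class HeptadAssignment:
    """Per-residue heptad letters with skip bookkeeping.

    ``letters`` maps each wild-type residue id to ``'a'``–``'g'`` or
    ``'skip'``.  ``anchors`` records the register anchors the assignment was
    propagated from.
    """

    letters: Mapping[int, str]
    skip_positions: tuple[int, ...] = ()
    anchors: Mapping[int, str] = field(default_factory=dict)

    @property
    def residue_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.letters))

    def positions_of(self, letter: str) -> tuple[int, ...]:
        """All residue ids assigned the given heptad letter."""
        return tuple(r for r in self.residue_ids if self.letters[r] == letter)


def assign_heptad_register(
    residue_ids: Sequence[int],
    anchors: Mapping[int, str],
    skip_positions: Iterable[int] = (),
) -> HeptadAssignment:
    """Propagate heptad letters cyclically from anchors, pausing at skips.

    Parameters
    ----------
    residue_ids:
        Ordered wild-type residue ids of the chain (gaps allowed for
        deletions; a deleted residue simply consumes no register step).
    anchors:
        Mapping of residue id to heptad letter.  All anchors must imply the
        same register phase or :class:`RegisterConflictError` is raised.
    skip_positions:
        Residue ids labelled ``'skip'``; the cyclic counter does not advance
        across them, so the residue after a skip continues where the residue
        before it left off.
    """
    ids = list(residue_ids)
    if not ids:
        raise ValueError("empty residue id list")
    skips = set(skip_positions)
    if not skips <= set(ids):
        raise ValueError(f"skip positions {sorted(skips - set(ids))} outside the sequence")
    if not anchors:
        raise ValueError("at least one register anchor is required")

    # Register index: counts non-skip residues in chain order.
    reg_index: dict[int, int] = {}
    k = 0
    for rid in ids:
        if rid in skips:
            continue
        reg_index[rid] = k
        k += 1

    offsets = set()
    for rid, letter in anchors.items():
        if rid in skips:
            raise RegisterConflictError(f"anchor {rid} is a skip residue")
        if rid not in reg_index:
            raise ValueError(f"anchor residue {rid} not in sequence")
        offsets.add((HEPTAD_LETTERS.index(letter) - reg_index[rid]) % 7)
    if len(offsets) > 1:
        raise RegisterConflictError(f"anchors imply conflicting register phases: {anchors}")
    offset = offsets.pop()

    letters = {
        rid: ("skip" if rid in skips else HEPTAD_LETTERS[(reg_index[rid] + offset) % 7])
        for rid in ids
    }
    return HeptadAssignment(letters, tuple(sorted(skips)), dict(anchors))


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)(del|[A-Z])$")


def mutate_sequence(sequence: NumberedSequence, spec: str) -> NumberedSequence:
    """Apply a point substitution or single-residue deletion.

    ``spec`` is the conventional short form, e.g. ``"A1603P"`` (Ala1603→Pro)
    or ``"K1617del"`` (Lys1617 deleted).  An empty spec returns the sequence
    unchanged.  Substitutions preserve length; deletions shorten the chain by
    one and leave a gap in the wild-type numbering.
    """
    if not spec:
        return sequence
    m = _MUTATION_RE.match(spec)
    if m is None:
        raise MutationError(f"cannot parse mutation spec {spec!r}")
    wt_aa, resid, new = m.group(1), int(m.group(2)), m.group(3)
    try:
        idx = sequence.numbering.index(resid)
    except ValueError:
        raise MutationError(f"residue {resid} not present in the sequence") from None
    if sequence.seq[idx] != wt_aa:
        raise MutationError(
            f"mutation {spec}: sequence has {sequence.seq[idx]} at {resid}, expected {wt_aa}"
        )
    if new == "del":
        return NumberedSequence(
            sequence.seq[:idx] + sequence.seq[idx + 1 :],
            sequence.numbering[:idx] + sequence.numbering[idx + 1 :],
        )
    return NumberedSequence(
        sequence.seq[:idx] + new + sequence.seq[idx + 1 :], sequence.numbering
    )
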