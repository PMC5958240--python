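"""SYNTHETIC stand-in sequence for the β-MHC rod region 1526–1689.

No sequence accession is shipped with this package, so the wild-type chain
used by the builder and the synthetic-data generators is a synthetic
coiled-coil sequence, NOT the human MYH7 sequence.  Every residue identity
that the analyses rely upon is pinned at its published position (UniProt-style
numbering of the β-cardiac myosin heavy chain):

* F1565, V1594, L1601, L1629 — heptad ``a`` anchors bounding the
  non-canonical motif spans,
* E1582 — the third rod skip residue,
* A1603 (mutated to proline in A1603P), E1604 (``d``), S1607, R1608 (``a``),
* V1614, K1615 (``a``), K1616, K1617 (deleted in K1617del), E1619, D1621.

All remaining positions are filled with heptad-appropriate residues
(hydrophobic at ``a``/``d``, charged/polar elsewhere), so the stand-in has
the composition statistics of a genuine left-handed dimeric coiled coil.
Users with the real sequence can pass it anywhere this one is accepted.
"""

from __future__ import annotations

from myotail.register import NumberedSequence, assign_heptad_register

#: First and last residue (inclusive) of the composite-model region.
REGION_START = 1526
REGION_END = 1689

#: The third skip residue of the β-MHC rod, inside the modeled region.
SKIP_RESIDUE = 1582

#: Heptad register anchor consistent with every position the analyses name:
#: propagating a→g from L1601 ``a`` (pausing at the skip) puts F1565 and
#: V1594 at ``a``, E1604 at ``d``, R1608 and K1615 at ``a``.
REGISTER_ANCHORS = {1601: "a"}

#: Residue identities pinned at their published positions.
PINNED_RESIDUES = {
    1565: "F",
    1582: "E",   # skip residue
    1594: "V",
    1601: "L",
    1603: "A",
    1604: "E",
    1607: "S",
    1608: "R",
    1614: "V",
    1615: "K",
    1616: "K",
    1617: "K",
    1619: "E",
    1621: "D",
    1629: "L",
}

# Filler identity per heptad position: hydrophobic core at a/d, charged at
# e/g (salt-bridge prone), polar/charged at the solvent-exposed b/c/f.
_FILLER = {"a": "L", "b": "Q", "c": "A", "d": "L", "e": "E", "f": "R", "g": "K"}


def wild_type_sequence() -> NumberedSequence:
    """Return the synthetic stand-in wild-type chain for residues 1526–1689.

    The sequence is generated from the heptad register so that every ``a``/``d``
    position is hydrophobic and the pinned residues sit at their published
    positions.  The skip residue E1582 is included (164 residues in total).
    """
    residue_ids = list(range(REGION_START, REGION_END + 1))
    assignment = assign_heptad_register(residue_ids, REGISTER_ANCHORS, skip_positions=(SKIP_RESIDUE,))
    letters = assignment.letters
    seq = []
    for rid in residue_ids:
        if rid in PINNED_RESIDUES:
            seq.append(PINNED_RESIDUES[rid])
        elif letters[rid] == "skip":
            seq.append("E")
        else:
            seq.append(_FILLER[letters[rid]])
    return NumberedSequence("".join(seq), tuple(residue_ids))
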