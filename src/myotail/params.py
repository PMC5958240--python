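"""Crick parameterization constants for two-strand coiled-coil building.

The defaults describe the β-cardiac myosin rod coiled coil: a right-handed
α-helix with 3.617 residues per turn and a 1.495 Å axial translation per
residue, wound into a left-handed supercoil of 4.9 Å major radius, with the
two strands placed antipodally about the supercoil axis and a 210° helix
self-rotation phase.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CrickParams:
    """Geometric parameters of the generalized Crick coiled-coil model.

    Attributes
    ----------
    residues_per_turn:
        Intrinsic residues per turn of the α-helix (dimensionless, > 3).
    rise_per_residue:
        Axial translation per residue along the supercoil axis, in Å.
    strand_phase:
        Helix self-rotation phase in degrees, applied identically to both
        strands; the strands themselves sit 180° apart about the supercoil
        axis.  Must lie in [0, 360).
    major_radius:
        Radius of the superhelical path of each helix axis, in Å.
    minor_radius:
        Radius of the Cα circle about the local helix axis, in Å.
    smoothing_b:
        Width of the logistic blend between adjacent motif phase rates,
        as a fraction of motif length (dimensionless).
    """

    residues_per_turn: float = 3.617
    rise_per_residue: float = 1.495
    strand_phase: float = 210.0
    major_radius: float = 4.9
    minor_radius: float = 2.26
    smoothing_b: float = 0.03

    def __post_init__(self) -> None:
        if not self.residues_per_turn > 3:
            raise ValueError(f"residues_per_turn must exceed 3, got {self.residues_per_turn}")
        for name in ("rise_per_residue", "major_radius", "minor_radius", "smoothing_b"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if not 0 <= self.strand_phase < 360:
            raise ValueError(f"strand_phase must lie in [0, 360), got {self.strand_phase}")

    @property
    def intrinsic_rate_deg(self) -> float:
        """Intrinsic helix rotation per residue, degrees (360 / residues-per-turn)."""
        return 360.0 / self.residues_per_turn
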