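"""Parametric (Crick) construction of two-chain coiled-coil backbones.

A model is generated residue by residue along a straight supercoil axis
(the z axis).  Each motif of the schedule prescribes a local helix phase
rate of ``360·N/length`` degrees per residue measured in the frame that
co-rotates with the supercoil; the intrinsic helix rate is
``360 / residues_per_turn``.  The difference is absorbed as supercoil
twist, so canonical heptads (2 turns / 7 residues) wind a left-handed
supercoil, the 29-residue skip motif (8 turns) locally unwinds it to nearly
zero twist, and the 27-residue deletion motif (8 turns) locally overwinds
it.  Transitions between motif rates are blended by logistic ramps of width
``smoothing_b × motif length``.  The two chains are antipodal about the
supercoil axis and share the same helix self-rotation phase, giving exact
C2 symmetry; the phase origin is chosen so that heptad ``a`` residues sit
at ``strand_phase`` degrees from the outward radial, which buries the
``a``/``d`` seam between the helices.

Backbone N, C and O atoms are completed from an ideal α-helix template
rigidly fitted to each residue's local Cα triad; no side chains are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from myotail.geometry import ideal_helix_backbone, kabsch
from myotail.motifs import MotifSchedule
from myotail.params import CrickParams
from myotail.register import HeptadAssignment, NumberedSequence

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class BuildError(ValueError):
    """Raised when a schedule/sequence mismatch or bad geometry is detected."""


@dataclass
class CoiledCoilModel:
    """Two-chain coiled-coil backbone with its provenance metadata.

    ``coords[chain][atom]`` is an (n_res, 3) array in Å for chains ``"A"``
    and ``"B"``; residue order matches ``sequences[chain].numbering``
    (wild-type numbering, with a gap at any deleted position).
    """

    sequences: Mapping[str, NumberedSequence]
    coords: Mapping[str, Mapping[str, np.ndarray]]
    assignment: HeptadAssignment | None
    schedule: MotifSchedule
    params: CrickParams
    metadata: dict = field(default_factory=dict)

    @property
    def chains(self) -> tuple[str, ...]:
        return tuple(self.coords)

    def ca(self, chain: str) -> np.ndarray:
        """Cα trace of one chain, (n_res, 3)."""
        return self.coords[chain]["CA"]

    def n_residues(self, chain: str = "A") -> int:
        return len(self.sequences[chain])

    def axis_length(self) -> float:
        """End-to-end extent along the supercoil (z) axis, Å."""
        z = self.ca("A")[:, 2]
        return float(z[-1] - z[0])


def _rate_function(schedule: MotifSchedule, b: float) -> "tuple[np.ndarray, np.ndarray]":
    """Per-step and per-residue smoothed phase rates (deg/residue).

    Returns ``(step_rates, residue_rates)``: ``step_rates[i]`` applies to
    the bond between residues i and i+1 (evaluated at index i + 0.5), and
    ``residue_rates[i]`` is the instantaneous rate at residue i (used for
    the analytic tangent).
    """
    lengths = np.array([m.length for m in schedule.motifs], dtype=float)
    rates = np.array([m.phase_rate_deg for m in schedule.motifs])
    boundaries = np.cumsum(lengths)[:-1]  # transition positions in residue index units
    widths = b * 0.5 * (lengths[:-1] + lengths[1:])
    widths = np.maximum(widths, 1e-6)

    def rate(t: np.ndarray) -> np.ndarray:
        out = np.full_like(t, rates[0], dtype=float)
        for k in range(len(boundaries)):
            out += (rates[k + 1] - rates[k]) * expit((t - boundaries[k]) / widths[k])
        return out

    n = schedule.total_length
    return rate(np.arange(n - 1) + 0.5), rate(np.arange(n, dtype=float))


def build_coiled_coil(
    seq_a: NumberedSequence,
    seq_b: NumberedSequence,
    schedule: MotifSchedule,
    params: CrickParams = CrickParams(),
    assignment: HeptadAssignment | None = None,
) -> CoiledCoilModel:
    """Generate a two-chain backbone model from sequence + motif schedule.

    Both chains must have the schedule's residue count (parallel homodimer).
    If ``assignment`` is given, the minor-helix phase origin is anchored so
    the first heptad ``a`` residue sits at ``params.strand_phase``;
    otherwise the first residue does.
    """
    n = len(seq_a)
    if len(seq_b) != n:
        raise BuildError(f"chain lengths differ: {n} vs {len(seq_b)}")
    if schedule.total_length != n:
        raise BuildError(
            f"schedule covers {schedule.total_length} residues but chains have {n}"
        )

    step_rates, residue_rates = _rate_function(schedule, params.smoothing_b)
    intrinsic = params.intrinsic_rate_deg

    # Cumulative phases (degrees). psi: minor-helix phase in the co-rotating
    # frame; phi: supercoil azimuth of the helix axis.
    psi = np.concatenate([[0.0], np.cumsum(step_rates)])
    phi = np.concatenate([[0.0], np.cumsum(intrinsic - step_rates)])

    anchor = 0
    if assignment is not None:
        a_pos = [i for i, rid in enumerate(seq_a.numbering) if assignment.letters.get(rid) == "a"]
        if a_pos:
            anchor = a_pos[0]
    psi = psi - psi[anchor] + params.strand_phase

    z = np.arange(n) * params.rise_per_residue
    phi_rad = np.deg2rad(phi)
    psi_rad = np.deg2rad(psi)
    dphi = np.deg2rad(intrinsic - residue_rates)  # rad per residue, for the tangent

    coords: dict[str, dict[str, np.ndarray]] = {}
    for chain, offset in (("A", 0.0), ("B", np.pi)):
        az = phi_rad + offset
        axis = np.column_stack(
            [params.major_radius * np.cos(az), params.major_radius * np.sin(az), z]
        )
        # Analytic tangent of the axis curve and a perpendicular radial frame.
        tangent = np.column_stack(
            [
                -params.major_radius * np.sin(az) * dphi,
                params.major_radius * np.cos(az) * dphi,
                np.full(n, params.rise_per_residue),
            ]
        )
        tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
        radial = np.column_stack([np.cos(az), np.sin(az), np.zeros(n)])
        radial -= np.sum(radial * tangent, axis=1, keepdims=True) * tangent
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        binormal = np.cross(tangent, radial)
        ca = axis + params.minor_radius * (
            np.cos(psi_rad)[:, None] * radial + np.sin(psi_rad)[:, None] * binormal
        )
        coords[chain] = {"CA": ca}

    _complete_backbone(coords)

    for chain in coords:
        for atom, xyz in coords[chain].items():
            if not np.all(np.isfinite(xyz)):
                raise BuildError(f"non-finite coordinates in chain {chain} atom {atom}")
        d = np.linalg.norm(np.diff(coords[chain]["CA"], axis=0), axis=1)
        if np.any(np.abs(d - 3.80) > 0.10):
            raise BuildError(
                f"chain {chain}: consecutive Cα distance outside 3.80 ± 0.10 Å "
                f"(range {d.min():.3f}–{d.max():.3f})"
            )

    return CoiledCoilModel(
        sequences={"A": seq_a, "B": seq_b},
        coords=coords,
        assignment=assignment,
        schedule=schedule,
        params=params,
        metadata={"builder": "crick", "n_residues": n},
    )


def _complete_backbone(coords: dict[str, dict[str, np.ndarray]]) -> None:
    """Place N, C, O by fitting an ideal α-helix template to each Cα triad."""
    template = ideal_helix_backbone(5)
    t_ca = template["CA"]
    for chain_coords in coords.values():
        ca = chain_coords["CA"]
        n = len(ca)
        out = {atom: np.empty((n, 3)) for atom in ("N", "C", "O")}
        for i in range(n):
            if i == 0:
                tpl_idx, ctr = (0, 1, 2), 0
                target = ca[0:3]
            elif i == n - 1:
                tpl_idx, ctr = (2, 3, 4), 4
                target = ca[n - 3 : n]
            else:
                tpl_idx, ctr = (1, 2, 3), 2
                target = ca[i - 1 : i + 2]
            R, t, _ = kabsch(t_ca[list(tpl_idx)], target)
            for atom in ("N", "C", "O"):
                out[atom][i] = template[atom][ctr] @ R.T + t
        chain_coords.update(out)
        # Canonical atom order for consumers that iterate.
        chain_coords_items = {a: chain_coords[a] for a in BACKBONE_ATOMS}
        chain_coords.clear()
        chain_coords.update(chain_coords_items)
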