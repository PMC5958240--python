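"""Small structural-geometry utilities shared across the package.

Provides internal-coordinate (NeRF) peptide-backbone construction — used both
for the ideal α-helix template that completes builder backbones and for the
extended Gly-X-Gly reference peptides of the solvent-accessibility module —
and mass-unweighted Kabsch superposition.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

# Backbone internal coordinates (Engh & Huber-style ideal values, Å / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

# Ideal α-helix and extended-strand dihedrals.
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 140.0


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from three predecessors by bond length, angle and torsion.

    ``angle`` is the b–c–d angle and ``torsion`` the a–b–c–d dihedral, both in
    degrees (natural extension reference frame method).
    """
    ang, tor = np.deg2rad(angle), np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_from_dihedrals(phi_psi: "list[tuple[float, float]]") -> dict[str, np.ndarray]:
    """Build an all-trans peptide backbone (N, CA, C, O) from (φ, ψ) pairs.

    Returns arrays of shape (n_res, 3) per atom name.  The first residue's φ
    and the last residue's ψ torsions are still used to place C and O, so the
    chain has exactly ``len(phi_psi)`` complete residues.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    # Seed the first residue in a canonical local frame.
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            N[i] = nerf(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, phi_psi[i - 1][1])
            CA[i] = nerf(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
            C[i] = nerf(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi)
        O[i] = nerf(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def ideal_helix_backbone(n_res: int) -> dict[str, np.ndarray]:
    """Ideal α-helical backbone (φ = −57°, ψ = −47°)."""
    return backbone_from_dihedrals([(HELIX_PHI, HELIX_PSI)] * n_res)


def extended_backbone(n_res: int) -> dict[str, np.ndarray]:
    """Extended-strand backbone (φ = −120°, ψ = 140°) for reference peptides."""
    return backbone_from_dihedrals([(EXTENDED_PHI, EXTENDED_PSI)] * n_res)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target`` (both (n, 3)).

    Returns ``(rotation_matrix, translation, rmsd)`` such that
    ``mobile @ R.T + t`` best fits ``target`` in the least-squares sense
    (mass-unweighted Kabsch solution).
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    moved = (mobile - mc) @ R.T + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, tc - mc @ R.T, rmsd


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Superpose and return the transformed coordinates plus the RMSD."""
    R, t, rmsd = kabsch(mobile, target)
    return mobile @ R.T + t, rmsd
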